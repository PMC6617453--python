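"""Hard exclusion cascade for annotated exome variants.

Six rules, applied in a fixed audited order but with every rule evaluated
for every variant (the verdict is order-independent):

1. ``depth``      — per-sample genotypes with depth below ``min_depth``
                    (default 10 reads) are masked to missing; the variant
                    falls only if every carrier genotype is masked.  A
                    strict site-level mode excludes the variant whenever
                    any sequenced sample is under-covered.
2. ``segdup``     — variants in segmentally duplicated regions fall.
3. ``frequency``  — any population frequency (1000 Genomes overall/East
                    Asian, ESP6500, ExAC overall/East Asian) above
                    ``max_pop_af`` (default 0.5%) fails; unobserved
                    (missing) frequencies count as 0.
4. ``inhouse``    — seen in more than ``max_inhouse_nonnpc_families``
                    (default 3) non-study families, or in more than
                    ``max_inhouse_npc_individuals`` (default 50) study
                    individuals.
5. ``functional`` — only nonsynonymous, inframe indel, frameshift,
                    nonsense and splicing consequences are retained.
6. ``cadd``       — CADD phred score must reach ``cadd_min`` (default 15);
                    a missing score fails because deleteriousness cannot
                    be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from .variants import AnnotatedVariant, AnnotationError, Consequence, Genotype

__all__ = [
    "FilterConfig",
    "FilterAudit",
    "RULE_ORDER",
    "RETAINED_CONSEQUENCES",
    "depth_mask",
    "depth_filter",
    "frequency_filter",
    "inhouse_filter",
    "segdup_filter",
    "functional_filter",
    "cadd_filter",
    "apply_hard_filters",
]

RULE_ORDER = ("depth", "segdup", "frequency", "inhouse", "functional", "cadd")

RETAINED_CONSEQUENCES = frozenset(
    {
        Consequence.NONSYNONYMOUS,
        Consequence.INFRAME_INDEL,
        Consequence.FRAMESHIFT,
        Consequence.NONSENSE,
        Consequence.SPLICING,
    }
)


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 10
    max_pop_af: float = 0.005
    max_inhouse_nonnpc_families: int = 3
    max_inhouse_npc_individuals: int = 50
    cadd_min: float = 15.0
    retained_consequences: frozenset[Consequence] = RETAINED_CONSEQUENCES
    depth_mode: str = "mask"  # "mask" | "site"

    def __post_init__(self) -> None:
        if self.depth_mode not in ("mask", "site"):
            raise ValueError(f"depth_mode must be 'mask' or 'site', got {self.depth_mode!r}")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "FilterConfig":
        kwargs = dict(mapping)
        if "retained_consequences" in kwargs:
            kwargs["retained_consequences"] = frozenset(
                Consequence.from_string(c) for c in kwargs["retained_consequences"]
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_mapping(data.get("filters", data))


@dataclass
class FilterAudit:
    """Per-variant record of every rule result and the overall verdict."""

    key: tuple
    verdict: str  # "retained" | "excluded"
    first_failed_rule: str | None
    rule_results: dict[str, bool]
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Individual rules


def depth_mask(variant: AnnotatedVariant, min_depth: int = 10) -> AnnotatedVariant:
    """Mask genotypes of samples whose depth is below ``min_depth`` or missing."""
    masked = {}
    for sample, genotype in variant.site.genotypes.items():
        depth = variant.site.depths.get(sample)
        if depth is None or depth < min_depth:
            masked[sample] = Genotype.MISSING
        else:
            masked[sample] = genotype
    return variant.with_genotypes(masked)


def depth_filter(
    variant: AnnotatedVariant, min_depth: int = 10, mode: str = "mask"
) -> tuple[AnnotatedVariant, bool]:
    """Apply the depth rule; returns the masked variant and pass/fail.

    In ``mask`` mode the variant fails only when all of its carrier
    genotypes are masked away (a variant with no carriers passes
    vacuously).  In ``site`` mode any under-covered sample fails the site.
    """
    masked = depth_mask(variant, min_depth)
    if mode == "site":
        ok = all(
            d is not None and d >= min_depth for d in variant.site.depths.values()
        )
        return masked, ok
    carriers_before = variant.site.carriers()
    if not carriers_before:
        return masked, True
    return masked, any(masked.site.genotypes[s].carries for s in carriers_before)


def frequency_filter(variant: AnnotatedVariant, max_pop_af: float = 0.005) -> bool:
    """Pass unless any population frequency exceeds the cutoff (strict >)."""
    return not any(
        af is not None and af > max_pop_af
        for af in variant.annotation.population_frequencies
    )


def inhouse_filter(
    variant: AnnotatedVariant,
    max_nonnpc_families: int = 3,
    max_npc_individuals: int = 50,
) -> bool:
    ann = variant.annotation
    if ann.inhouse_non_npc_family_count < 0 or ann.inhouse_npc_individual_count < 0:
        raise AnnotationError(f"{variant.key}: negative in-house count")
    return (
        ann.inhouse_non_npc_family_count <= max_nonnpc_families
        and ann.inhouse_npc_individual_count <= max_npc_individuals
    )


def segdup_filter(variant: AnnotatedVariant) -> bool:
    """Fail iff the segmental-duplication flag is set; absent flag passes."""
    return not bool(variant.annotation.segdup)


def functional_filter(
    variant: AnnotatedVariant,
    retained: frozenset[Consequence] = RETAINED_CONSEQUENCES,
) -> bool:
    return variant.annotation.consequence in retained


def cadd_filter(variant: AnnotatedVariant, threshold: float = 15.0) -> bool:
    cadd = variant.annotation.cadd_phred
    return cadd is not None and cadd >= threshold


# ---------------------------------------------------------------------------
# Cascade


def apply_hard_filters(
    variants: Iterable[AnnotatedVariant],
    config: FilterConfig | None = None,
) -> tuple[list[AnnotatedVariant], list[FilterAudit]]:
    """Run every rule on every variant; retain those passing all rules.

    Returns the retained variants (with low-depth genotypes masked) and a
    complete audit.  ``first_failed_rule`` refers to the documented rule
    order; all rule results are recorded regardless.
    """
    config = config or FilterConfig()
    retained: list[AnnotatedVariant] = []
    audits: list[FilterAudit] = []
    for variant in variants:
        notes: list[str] = []
        masked, depth_ok = depth_filter(variant, config.min_depth, config.depth_mode)
        if variant.annotation.segdup is None:
            notes.append("segdup flag absent; treated as not duplicated")
        results = {
            "depth": depth_ok,
            "segdup": segdup_filter(variant),
            "frequency": frequency_filter(variant, config.max_pop_af),
            "inhouse": inhouse_filter(
                variant,
                config.max_inhouse_nonnpc_families,
                config.max_inhouse_npc_individuals,
            ),
            "functional": functional_filter(variant, config.retained_consequences),
            "cadd": cadd_filter(variant, config.cadd_min),
        }
        first_failed = next((r for r in RULE_ORDER if not results[r]), None)
        if first_failed is None:
            retained.append(masked)
        audits.append(
            FilterAudit(
                key=variant.key,
                verdict="retained" if first_failed is None else "excluded",
                first_failed_rule=first_failed,
                rule_results=results,
                notes=notes,
            )
        )
    return retained, audits
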