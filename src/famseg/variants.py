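"""Multi-sample genotype input, allele normalization, and annotation joining.

Multi-allelic VCF records are decomposed into one site per alternate
allele; indel alleles are left-normalized by trimming the shared suffix
and then the shared prefix, always keeping a one-base anchor.  Under the
dominant model used downstream, "carries the variant" means heterozygous
or homozygous alternate — zygosity is otherwise irrelevant.

The annotation table stands in for an exome annotation pipeline and is a
TSV keyed on normalized alleles with the header::

    CHROM POS REF ALT GENE CONSEQUENCE CADD_PHRED AF_1KG_ALL AF_1KG_EAS
    AF_ESP6500 AF_EXAC_ALL AF_EXAC_EAS SEGDUP INHOUSE_NONNPC_FAM INHOUSE_NPC_IND
"""

from __future__ import annotations

import enum
import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "Genotype",
    "Consequence",
    "VariantKey",
    "VariantSite",
    "AnnotationRecord",
    "AnnotatedVariant",
    "JoinAudit",
    "VcfParseError",
    "AnnotationError",
    "normalize_allele",
    "read_vcf",
    "read_annotations",
    "join_annotations",
    "ANNOTATION_COLUMNS",
]

VariantKey = tuple[str, int, str, str]


class VcfParseError(ValueError):
    pass


class AnnotationError(ValueError):
    pass


class Genotype(enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


class Consequence(enum.Enum):
    SYNONYMOUS = "synonymous"
    NONSYNONYMOUS = "nonsynonymous"
    INFRAME_INDEL = "inframe_indel"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    SPLICING = "splicing"
    OTHER = "other"

    @classmethod
    def from_string(cls, value: str) -> "Consequence":
        token = value.strip().lower().replace(" ", "_").replace("-", "_")
        aliases = {
            "missense": cls.NONSYNONYMOUS,
            "stopgain": cls.NONSENSE,
            "stop_gain": cls.NONSENSE,
            "splice": cls.SPLICING,
            "splice_variant": cls.SPLICING,
            "nonframeshift_deletion": cls.INFRAME_INDEL,
            "nonframeshift_insertion": cls.INFRAME_INDEL,
            "inframe_deletion": cls.INFRAME_INDEL,
            "inframe_insertion": cls.INFRAME_INDEL,
        }
        if token in aliases:
            return aliases[token]
        try:
            return cls(token)
        except ValueError:
            return cls.OTHER


@dataclass(frozen=True)
class VariantSite:
    """One normalized alternate allele with per-sample genotypes and depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: Mapping[str, Genotype] = field(default_factory=dict)
    depths: Mapping[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    def carriers(self) -> list[str]:
        return [s for s, g in self.genotypes.items() if g.carries]


@dataclass(frozen=True)
class AnnotationRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Consequence
    cadd_phred: float | None
    af_kg_all: float | None = None
    af_kg_eas: float | None = None
    af_esp6500: float | None = None
    af_exac_all: float | None = None
    af_exac_eas: float | None = None
    segdup: bool | None = False
    inhouse_non_npc_family_count: int = 0
    inhouse_npc_individual_count: int = 0

    def __post_init__(self) -> None:
        for name in ("af_kg_all", "af_kg_eas", "af_esp6500", "af_exac_all", "af_exac_eas"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise AnnotationError(f"{self.key}: {name}={v} outside [0, 1]")
        for name in ("inhouse_non_npc_family_count", "inhouse_npc_individual_count"):
            if getattr(self, name) < 0:
                raise AnnotationError(f"{self.key}: negative {name}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def population_frequencies(self) -> tuple[float | None, ...]:
        return (self.af_kg_all, self.af_kg_eas, self.af_esp6500,
                self.af_exac_all, self.af_exac_eas)


@dataclass(frozen=True)
class AnnotatedVariant:
    site: VariantSite
    annotation: AnnotationRecord

    def __post_init__(self) -> None:
        if self.site.key != self.annotation.key:
            raise ValueError(
                f"annotation key {self.annotation.key} does not match site {self.site.key}"
            )

    @property
    def key(self) -> VariantKey:
        return self.site.key

    @property
    def gene(self) -> str:
        return self.annotation.gene

    def with_genotypes(self, genotypes: Mapping[str, Genotype]) -> "AnnotatedVariant":
        return AnnotatedVariant(replace(self.site, genotypes=dict(genotypes)), self.annotation)


# ---------------------------------------------------------------------------
# Allele normalization


def normalize_allele(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-normalize: trim the common suffix, then the common prefix.

    A one-base anchor is always kept; trimming the prefix advances the
    1-based position accordingly.
    """
    if not ref or not alt:
        raise ValueError("empty allele")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# ---------------------------------------------------------------------------
# VCF input


def _structural_check(path: Path) -> None:
    """Cheap line-by-line sanity check so malformed input fails with a line number."""
    opener = gzip.open if str(path).endswith(".gz") else open
    n_columns: int | None = None
    saw_header = False
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                n_columns = len(line.rstrip("\n").split("\t"))
                if n_columns < 8:
                    raise VcfParseError(f"{path}: line {lineno}: truncated #CHROM header")
                continue
            if not saw_header:
                raise VcfParseError(f"{path}: line {lineno}: data before #CHROM header")
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_columns:
                raise VcfParseError(
                    f"{path}: line {lineno}: expected {n_columns} columns, got {len(fields)}"
                )
            if not fields[1].isdigit():
                raise VcfParseError(f"{path}: line {lineno}: POS {fields[1]!r} is not an integer")
    if not saw_header:
        raise VcfParseError(f"{path}: missing #CHROM header line")


def read_vcf(path: str | Path) -> list[VariantSite]:
    """Read a VCF 4.x file into decomposed, normalized variant sites.

    Per-sample depth comes from FORMAT/DP when present (missing otherwise);
    genotypes with any missing allele decode as missing.
    """
    path = Path(path)
    _structural_check(path)
    try:
        vcf = VCF(str(path), gts012=False)
    except Exception as exc:  # pragma: no cover - htslib error paths
        raise VcfParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)
    sites: list[VariantSite] = []
    for record in vcf:
        try:
            raw = record.format("DP")
        except Exception:
            raw = None
        raw_depths = None if raw is None else raw.reshape(-1)
        genotype_rows = record.genotypes
        for alt_index, alt in enumerate(record.ALT, start=1):
            genotypes: dict[str, Genotype] = {}
            depths: dict[str, int | None] = {}
            for i, sample in enumerate(samples):
                alleles = [a for a in genotype_rows[i][:-1]]
                if not alleles or any(a < 0 for a in alleles):
                    genotypes[sample] = Genotype.MISSING
                else:
                    count = sum(1 for a in alleles if a == alt_index)
                    if count == 0:
                        genotypes[sample] = Genotype.HOM_REF
                    elif count == len(alleles):
                        genotypes[sample] = Genotype.HOM_ALT
                    else:
                        genotypes[sample] = Genotype.HET
                if raw_depths is None:
                    depths[sample] = None
                else:
                    d = int(raw_depths[i])
                    depths[sample] = None if d < 0 else d
            pos, ref, alt_norm = normalize_allele(record.POS, record.REF, alt)
            sites.append(
                VariantSite(
                    chrom=record.CHROM,
                    pos=pos,
                    ref=ref,
                    alt=alt_norm,
                    genotypes=genotypes,
                    depths=depths,
                )
            )
    return sites


# ---------------------------------------------------------------------------
# Annotation input and join

ANNOTATION_COLUMNS = [
    "CHROM", "POS", "REF", "ALT", "GENE", "CONSEQUENCE", "CADD_PHRED",
    "AF_1KG_ALL", "AF_1KG_EAS", "AF_ESP6500", "AF_EXAC_ALL", "AF_EXAC_EAS",
    "SEGDUP", "INHOUSE_NONNPC_FAM", "INHOUSE_NPC_IND",
]


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", ".", "NA"):
        return None
    return float(value)


def read_annotations(path: str | Path) -> dict[VariantKey, AnnotationRecord]:
    """Read the annotation TSV keyed on normalized alleles."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing annotation columns {missing}")
    records: dict[VariantKey, AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        segdup_raw = _opt_float(getattr(row, "SEGDUP"))
        record = AnnotationRecord(
            chrom=str(row.CHROM),
            pos=int(row.POS),
            ref=str(row.REF),
            alt=str(row.ALT),
            gene=str(row.GENE).upper(),
            consequence=Consequence.from_string(str(row.CONSEQUENCE)),
            cadd_phred=_opt_float(row.CADD_PHRED),
            af_kg_all=_opt_float(row.AF_1KG_ALL),
            af_kg_eas=_opt_float(row.AF_1KG_EAS),
            af_esp6500=_opt_float(row.AF_ESP6500),
            af_exac_all=_opt_float(row.AF_EXAC_ALL),
            af_exac_eas=_opt_float(row.AF_EXAC_EAS),
            segdup=None if segdup_raw is None else bool(segdup_raw),
            inhouse_non_npc_family_count=int(row.INHOUSE_NONNPC_FAM),
            inhouse_npc_individual_count=int(row.INHOUSE_NPC_IND),
        )
        if record.key in records:
            raise AnnotationError(f"{path}: duplicate annotation key {record.key}")
        records[record.key] = record
    return records


@dataclass
class JoinAudit:
    """Sites left unannotated and annotations matching no site."""

    unmatched_site_keys: list[VariantKey] = field(default_factory=list)
    unused_annotation_count: int = 0


def join_annotations(
    sites: Iterable[VariantSite],
    annotations: Mapping[VariantKey, AnnotationRecord],
) -> tuple[list[AnnotatedVariant], JoinAudit]:
    """Inner-join sites with their annotation records on the normalized key.

    Unmatched sites are excluded but recorded in the audit; annotation rows
    matching no site are counted as unused.
    """
    audit = JoinAudit()
    joined: list[AnnotatedVariant] = []
    seen: set[VariantKey] = set()
    for site in sites:
        record = annotations.get(site.key)
        if record is None:
            audit.unmatched_site_keys.append(site.key)
        else:
            joined.append(AnnotatedVariant(site, record))
            seen.add(site.key)
    audit.unused_annotation_count = sum(1 for k in annotations if k not in seen)
    return joined, audit
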