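"""Dominant-model co-segregation within families and cross-family rules.

A variant co-segregates in a family when every sequenced affected member
and every sequenced obligate carrier carries it (a masked/missing genotype
in any required carrier defeats co-segregation); in strict mode no
sequenced unaffected blood relative may carry it.  A variant qualifies

* by ``rule1`` when it co-segregates in at least one configuration-A
  family (3+ affected, or 2 affected plus an obligate carrier);
* else by ``rule2`` when it co-segregates in at least one
  configuration-B family (an affected pair that is neither siblings nor
  parent-child, with an unaffected blood relative sequenced);
* else by ``rule3`` when it co-segregates in at least two
  configuration-C families (affected sibling or parent-child pairs).

Families in which the variant is absent from every sequenced member
contribute nothing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .pedigree import (
    Affection,
    Family,
    FamilyConfiguration,
    classify_family_configuration,
    resolve_obligate_carriers,
)
from .variants import AnnotatedVariant, VariantKey

__all__ = [
    "Rule",
    "CarrierCounts",
    "SegregationEvidence",
    "CandidateVariant",
    "CohortConsistencyError",
    "family_carrier_status",
    "family_cosegregates",
    "evaluate_variant",
    "run_segregation",
    "aggregate_by_gene",
]


class CohortConsistencyError(ValueError):
    """A sequenced pedigree member is absent from the genotype data."""


class Rule(enum.Enum):
    RULE1 = "rule1"
    RULE2 = "rule2"
    RULE3 = "rule3"
    NONE = "none"


@dataclass(frozen=True)
class CarrierCounts:
    """Carrier tallies among a family's sequenced members."""

    affected_carriers: int
    affected_total: int
    obligate_carriers: int
    obligate_total: int
    unaffected_carriers: int
    unaffected_total: int
    carrier_map: Mapping[str, bool] = field(default_factory=dict)

    @property
    def any_carrier(self) -> bool:
        return any(self.carrier_map.values())


@dataclass
class SegregationEvidence:
    key: VariantKey
    qualifies: bool
    rule_used: Rule
    supporting_families: list[str]
    family_detail: dict[str, CarrierCounts] = field(default_factory=dict)


@dataclass
class CandidateVariant:
    """A variant that survived the hard filters and qualifies by segregation."""

    variant: AnnotatedVariant
    evidence: SegregationEvidence

    @property
    def key(self) -> VariantKey:
        return self.variant.key

    @property
    def gene(self) -> str:
        return self.variant.gene


def family_carrier_status(
    variant: AnnotatedVariant,
    family: Family,
    obligates: set[str] | None = None,
) -> CarrierCounts:
    """Carrier map and tallies restricted to sequenced family members.

    The unaffected tally counts sequenced unaffected blood relatives that
    are not obligate carriers (married-in relatives are excluded from it).
    Members with a missing genotype count in their group total but never
    as carriers.
    """
    if obligates is None:
        obligates = resolve_obligate_carriers(family)
    blood = family.blood_relatives()
    carrier_map: dict[str, bool] = {}
    aff_c = aff_t = obl_c = obl_t = una_c = una_t = 0
    for pid, ind in family.members.items():
        if not ind.sequenced:
            continue
        if pid not in variant.site.genotypes:
            raise CohortConsistencyError(
                f"sequenced member {pid!r} of family {family.family_id} "
                "is absent from the genotype data"
            )
        carries = variant.site.genotypes[pid].carries
        carrier_map[pid] = carries
        if ind.affection is Affection.AFFECTED:
            aff_t += 1
            aff_c += carries
        elif pid in obligates:
            obl_t += 1
            obl_c += carries
        elif ind.affection is Affection.UNAFFECTED and pid in blood:
            una_t += 1
            una_c += carries
    return CarrierCounts(aff_c, aff_t, obl_c, obl_t, una_c, una_t, carrier_map)


def family_cosegregates(
    variant: AnnotatedVariant,
    family: Family,
    strict_unaffected: bool = False,
    obligates: set[str] | None = None,
    counts: CarrierCounts | None = None,
) -> bool:
    """True iff every sequenced affected member and obligate carrier carries.

    With ``strict_unaffected`` the variant must additionally be absent
    from every sequenced unaffected blood relative.
    """
    if counts is None:
        counts = family_carrier_status(variant, family, obligates)
    if counts.affected_total == 0:
        raise ValueError(
            f"family {family.family_id} has no sequenced affected member"
        )
    ok = (
        counts.affected_carriers == counts.affected_total
        and counts.obligate_carriers == counts.obligate_total
    )
    if strict_unaffected:
        ok = ok and counts.unaffected_carriers == 0
    return ok


def evaluate_variant(
    variant: AnnotatedVariant,
    families: Sequence[Family],
    strict_unaffected: bool = False,
    obligates_by_family: Mapping[str, set[str]] | None = None,
    configurations: Mapping[str, FamilyConfiguration] | None = None,
) -> SegregationEvidence:
    """Apply the three cross-family qualification rules to one variant."""
    if obligates_by_family is None:
        obligates_by_family = {
            fam.family_id: resolve_obligate_carriers(fam) for fam in families
        }
    if configurations is None:
        configurations = {
            fam.family_id: classify_family_configuration(
                fam, obligates_by_family[fam.family_id]
            )
            for fam in families
        }
    coseg: dict[FamilyConfiguration, list[str]] = {
        FamilyConfiguration.A: [],
        FamilyConfiguration.B: [],
        FamilyConfiguration.C: [],
    }
    detail: dict[str, CarrierCounts] = {}
    for fam in families:
        obligates = obligates_by_family[fam.family_id]
        counts = family_carrier_status(variant, fam, obligates)
        if not counts.any_carrier:
            continue  # variant absent from the family: contributes nothing
        detail[fam.family_id] = counts
        config = configurations[fam.family_id]
        if config is FamilyConfiguration.UNINFORMATIVE or counts.affected_total == 0:
            continue
        if family_cosegregates(
            variant, fam, strict_unaffected, obligates, counts=counts
        ):
            coseg[config].append(fam.family_id)

    if coseg[FamilyConfiguration.A]:
        rule, supporting = Rule.RULE1, coseg[FamilyConfiguration.A]
    elif coseg[FamilyConfiguration.B]:
        rule, supporting = Rule.RULE2, coseg[FamilyConfiguration.B]
    elif len(coseg[FamilyConfiguration.C]) >= 2:
        rule, supporting = Rule.RULE3, coseg[FamilyConfiguration.C]
    else:
        rule, supporting = Rule.NONE, []
    return SegregationEvidence(
        key=variant.key,
        qualifies=rule is not Rule.NONE,
        rule_used=rule,
        supporting_families=sorted(supporting),
        family_detail=detail,
    )


def run_segregation(
    variants: Iterable[AnnotatedVariant],
    families: Sequence[Family],
    strict_unaffected: bool = False,
) -> tuple[list[CandidateVariant], list[SegregationEvidence]]:
    """Evaluate each variant; return qualifying candidates and all evidence."""
    obligates = {fam.family_id: resolve_obligate_carriers(fam) for fam in families}
    configurations = {
        fam.family_id: classify_family_configuration(fam, obligates[fam.family_id])
        for fam in families
    }
    candidates: list[CandidateVariant] = []
    evidence_list: list[SegregationEvidence] = []
    for variant in variants:
        evidence = evaluate_variant(
            variant, families, strict_unaffected, obligates, configurations
        )
        evidence_list.append(evidence)
        if evidence.qualifies:
            candidates.append(CandidateVariant(variant, evidence))
    return candidates, evidence_list


def aggregate_by_gene(
    candidates: Sequence[CandidateVariant],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level report: one row per candidate variant plus a gene summary.

    The ``COUNTS`` column follows the familiar affected/obligate/unaffected
    layout, summed over supporting families: affected carriers, obligate
    carriers, and unaffected blood relatives sequenced (carrier counts for
    unaffecteds are reported separately since published tables are
    ambiguous about which the third number is).
    """
    rows = []
    for cand in candidates:
        supporting = cand.evidence.supporting_families
        detail = [cand.evidence.family_detail[f] for f in supporting]
        aff = sum(c.affected_carriers for c in detail)
        obl = sum(c.obligate_carriers for c in detail)
        una_seq = sum(c.unaffected_total for c in detail)
        una_car = sum(c.unaffected_carriers for c in detail)
        rows.append(
            {
                "GENE": cand.gene,
                "CHROM": cand.variant.site.chrom,
                "POS": cand.variant.site.pos,
                "REF": cand.variant.site.ref,
                "ALT": cand.variant.site.alt,
                "CONSEQUENCE": cand.variant.annotation.consequence.value,
                "CADD_PHRED": cand.variant.annotation.cadd_phred,
                "RULE": cand.evidence.rule_used.value,
                "FAMILIES": ";".join(supporting),
                "N_AFFECTED_CARRIERS": aff,
                "N_OBLIGATE_CARRIERS": obl,
                "N_UNAFFECTED_SEQUENCED": una_seq,
                "N_UNAFFECTED_CARRIERS": una_car,
                "COUNTS": f"{aff}/{obl}/{una_seq}",
            }
        )
    columns = [
        "GENE", "CHROM", "POS", "REF", "ALT", "CONSEQUENCE", "CADD_PHRED",
        "RULE", "FAMILIES", "N_AFFECTED_CARRIERS", "N_OBLIGATE_CARRIERS",
        "N_UNAFFECTED_SEQUENCED", "N_UNAFFECTED_CARRIERS", "COUNTS",
    ]
    table = pd.DataFrame(rows, columns=columns)
    if not table.empty:
        table = table.sort_values(["GENE", "CHROM", "POS", "REF", "ALT"]).reset_index(
            drop=True
        )
        summary = (
            table.groupby("GENE")
            .agg(
                N_VARIANTS=("POS", "size"),
                N_FAMILIES=(
                    "FAMILIES",
                    lambda col: len(
                        {f for entry in col for f in entry.split(";") if f}
                    ),
                ),
            )
            .reset_index()
        )
    else:
        summary = pd.DataFrame(columns=["GENE", "N_VARIANTS", "N_FAMILIES"])
    return table, summary
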