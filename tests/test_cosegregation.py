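"""Within-family co-segregation and the cross-family qualification rules."""

from __future__ import annotations

import pytest

from famseg.cosegregation import (
    CohortConsistencyError,
    Rule,
    aggregate_by_gene,
    CandidateVariant,
    evaluate_variant,
    family_carrier_status,
    family_cosegregates,
    run_segregation,
)
from famseg.pedigree import Affection, Family, Sex
from famseg.variants import Genotype

from conftest import make_individual, make_variant


def trio3_family(fid="T3"):
    return Family.from_members(
        fid,
        [
            make_individual(f"{fid}_F", fid, sex=Sex.MALE, sequenced=False),
            make_individual(f"{fid}_M", fid, sex=Sex.FEMALE, sequenced=False),
            make_individual(
                f"{fid}_A1", fid, f"{fid}_F", f"{fid}_M", affection=Affection.AFFECTED
            ),
            make_individual(
                f"{fid}_A2", fid, f"{fid}_F", f"{fid}_M", affection=Affection.AFFECTED
            ),
            make_individual(
                f"{fid}_A3", fid, f"{fid}_F", f"{fid}_M", affection=Affection.AFFECTED
            ),
        ],
    )


def sibpair_family(fid):
    return Family.from_members(
        fid,
        [
            make_individual(f"{fid}_F", fid, sex=Sex.MALE, sequenced=False),
            make_individual(f"{fid}_M", fid, sex=Sex.FEMALE, sequenced=False),
            make_individual(
                f"{fid}_A1", fid, f"{fid}_F", f"{fid}_M", affection=Affection.AFFECTED
            ),
            make_individual(
                f"{fid}_A2", fid, f"{fid}_F", f"{fid}_M", affection=Affection.AFFECTED
            ),
        ],
    )


def obligate_family(fid="OB"):
    return Family.from_members(
        fid,
        [
            make_individual(f"{fid}_GP", fid, sex=Sex.MALE, affection=Affection.AFFECTED),
            make_individual(f"{fid}_GS", fid, sex=Sex.FEMALE, sequenced=False),
            make_individual(
                f"{fid}_MID", fid, f"{fid}_GP", f"{fid}_GS",
                affection=Affection.UNAFFECTED,
            ),
            make_individual(f"{fid}_SP", fid, sex=Sex.FEMALE, sequenced=False),
            make_individual(
                f"{fid}_C", fid, f"{fid}_MID", f"{fid}_SP",
                affection=Affection.AFFECTED,
            ),
        ],
    )


def bfam(fid="BF"):
    """Configuration-B avuncular family with sequenced unaffected sibling."""
    return Family.from_members(
        fid,
        [
            make_individual(f"{fid}_GF", fid, sex=Sex.MALE, sequenced=False),
            make_individual(f"{fid}_GM", fid, sex=Sex.FEMALE, sequenced=False),
            make_individual(
                f"{fid}_U", fid, f"{fid}_GF", f"{fid}_GM", affection=Affection.AFFECTED
            ),
            make_individual(
                f"{fid}_P", fid, f"{fid}_GF", f"{fid}_GM",
                affection=Affection.UNAFFECTED, sequenced=False,
            ),
            make_individual(f"{fid}_PS", fid, sex=Sex.MALE, sequenced=False),
            make_individual(
                f"{fid}_N", fid, f"{fid}_PS", f"{fid}_P", affection=Affection.AFFECTED
            ),
            make_individual(
                f"{fid}_N2", fid, f"{fid}_PS", f"{fid}_P",
                affection=Affection.UNAFFECTED,
            ),
        ],
    )


def genotypes_for(families, carriers, fill=Genotype.HOM_REF):
    g = {}
    for fam in families:
        for pid in fam.sequenced_ids():
            g[pid] = Genotype.HET if pid in carriers else fill
    return g


# ---------------------------------------------------------------------------
# Carrier status


def test_carrier_counts_all_affected_het():
    fam = trio3_family()
    v = make_variant(genotypes_for([fam], {"T3_A1", "T3_A2", "T3_A3"}))
    counts = family_carrier_status(v, fam)
    assert (counts.affected_carriers, counts.affected_total) == (3, 3)
    assert (counts.obligate_carriers, counts.obligate_total) == (0, 0)
    assert (counts.unaffected_carriers, counts.unaffected_total) == (0, 0)


def test_missing_genotype_counts_in_total_not_as_carrier():
    fam = trio3_family()
    g = genotypes_for([fam], {"T3_A1", "T3_A2"})
    g["T3_A3"] = Genotype.MISSING
    counts = family_carrier_status(make_variant(g), fam)
    assert (counts.affected_carriers, counts.affected_total) == (2, 3)


def test_unaffected_hom_alt_counts_as_carrier():
    fam = bfam()
    g = genotypes_for([fam], {"BF_U", "BF_N"})
    g["BF_N2"] = Genotype.HOM_ALT
    counts = family_carrier_status(make_variant(g), fam)
    assert counts.unaffected_carriers == 1


def test_sequenced_member_missing_from_vcf_is_an_error():
    fam = trio3_family()
    v = make_variant({"T3_A1": Genotype.HET})  # A2/A3 absent from genotype data
    with pytest.raises(CohortConsistencyError):
        family_carrier_status(v, fam)


# ---------------------------------------------------------------------------
# Within-family co-segregation


def test_cosegregates_with_all_required_carriers():
    fam = obligate_family()
    v = make_variant(genotypes_for([fam], {"OB_GP", "OB_MID", "OB_C"}))
    assert family_cosegregates(v, fam)


def test_one_affected_noncarrier_defeats_cosegregation():
    fam = trio3_family()
    v = make_variant(genotypes_for([fam], {"T3_A1", "T3_A2"}))
    assert not family_cosegregates(v, fam)


def test_missing_genotype_in_obligate_defeats_cosegregation():
    fam = obligate_family()
    g = genotypes_for([fam], {"OB_GP", "OB_C"})
    g["OB_MID"] = Genotype.MISSING
    assert not family_cosegregates(make_variant(g), fam)


def test_strict_unaffected_mode():
    fam = bfam()
    g = genotypes_for([fam], {"BF_U", "BF_N", "BF_N2"})
    v = make_variant(g)
    assert family_cosegregates(v, fam, strict_unaffected=False)
    assert not family_cosegregates(v, fam, strict_unaffected=True)


# ---------------------------------------------------------------------------
# Cross-family rules


def test_rule1_single_a_family():
    fam = trio3_family()
    v = make_variant(genotypes_for([fam], {"T3_A1", "T3_A2", "T3_A3"}))
    evidence = evaluate_variant(v, [fam])
    assert evidence.qualifies and evidence.rule_used is Rule.RULE1
    assert evidence.supporting_families == ["T3"]


def test_rule2_single_b_family():
    fam = bfam()
    v = make_variant(genotypes_for([fam], {"BF_U", "BF_N"}))
    evidence = evaluate_variant(v, [fam])
    assert evidence.qualifies and evidence.rule_used is Rule.RULE2


def test_single_c_family_does_not_qualify():
    fam = sibpair_family("C1")
    v = make_variant(genotypes_for([fam], {"C1_A1", "C1_A2"}))
    evidence = evaluate_variant(v, [fam])
    assert not evidence.qualifies and evidence.rule_used is Rule.NONE


def test_rule3_two_c_families():
    fams = [sibpair_family("C1"), sibpair_family("C2")]
    v = make_variant(genotypes_for(fams, {"C1_A1", "C1_A2", "C2_A1", "C2_A2"}))
    evidence = evaluate_variant(v, fams)
    assert evidence.qualifies and evidence.rule_used is Rule.RULE3
    assert len(evidence.supporting_families) == 2


def test_adding_supporting_family_never_revokes_qualification():
    fams = [trio3_family(), sibpair_family("C1")]
    carriers = {"T3_A1", "T3_A2", "T3_A3"}
    v1 = make_variant(genotypes_for(fams[:1], carriers))
    assert evaluate_variant(v1, fams[:1]).qualifies
    v2 = make_variant(genotypes_for(fams, carriers | {"C1_A1", "C1_A2"}))
    assert evaluate_variant(v2, fams).qualifies


def test_strict_candidates_subset_of_lenient():
    fam = bfam()
    carrier_sets = [
        {"BF_U", "BF_N"},
        {"BF_U", "BF_N", "BF_N2"},
        {"BF_U"},
    ]
    variants = [
        make_variant(genotypes_for([fam], c), pos=1000 + i)
        for i, c in enumerate(carrier_sets)
    ]
    lenient, _ = run_segregation(variants, [fam], strict_unaffected=False)
    strict, _ = run_segregation(variants, [fam], strict_unaffected=True)
    assert {c.key for c in strict} <= {c.key for c in lenient}
    assert len(lenient) == 2 and len(strict) == 1


# ---------------------------------------------------------------------------
# Gene aggregation


def test_aggregate_by_gene_summary():
    fams = [trio3_family(), sibpair_family("C1"), sibpair_family("C2")]
    v1 = make_variant(
        genotypes_for(fams, {"T3_A1", "T3_A2", "T3_A3"}), pos=100, gene="GENEX"
    )
    v2 = make_variant(
        genotypes_for(fams, {"C1_A1", "C1_A2", "C2_A1", "C2_A2"}),
        pos=200,
        gene="GENEX",
    )
    candidates, _ = run_segregation([v1, v2], fams)
    table, summary = aggregate_by_gene(candidates)
    assert len(table) == 2
    assert summary.loc[0, "GENE"] == "GENEX"
    assert summary.loc[0, "N_VARIANTS"] == 2
    assert summary.loc[0, "N_FAMILIES"] == 3
    row = table[table["POS"] == 100].iloc[0]
    assert row["COUNTS"] == "3/0/0"


def test_aggregate_empty():
    table, summary = aggregate_by_gene([])
    assert table.empty and summary.empty
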