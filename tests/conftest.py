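from __future__ import annotations

import pathlib
import sys

import pytest

sys.path.insert(0, str(pathlib.Path(__file__).parent))  # for oracles.py

from famseg.pedigree import Affection, Family, Individual, Sex
from famseg.variants import (
    AnnotatedVariant,
    AnnotationRecord,
    Consequence,
    Genotype,
    VariantSite,
)


def make_individual(
    pid,
    fid="FAM1",
    father=None,
    mother=None,
    sex=Sex.UNKNOWN,
    affection=Affection.UNKNOWN,
    sequenced=True,
    obligate=False,
):
    return Individual(
        person_id=pid,
        family_id=fid,
        father_id=father,
        mother_id=mother,
        sex=sex,
        affection=affection,
        sequenced=sequenced,
        declared_obligate=obligate,
    )


def make_variant(
    genotypes: dict[str, Genotype],
    depths: dict[str, int | None] | None = None,
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    gene="GENE1",
    consequence=Consequence.NONSYNONYMOUS,
    cadd=25.0,
    afs=(0.0, 0.0, 0.0, 0.0, 0.0),
    segdup=False,
    inhouse_fam=0,
    inhouse_npc=0,
) -> AnnotatedVariant:
    if depths is None:
        depths = {s: 50 for s in genotypes}
    site = VariantSite(
        chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=genotypes, depths=depths
    )
    ann = AnnotationRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence=consequence,
        cadd_phred=cadd,
        af_kg_all=afs[0],
        af_kg_eas=afs[1],
        af_esp6500=afs[2],
        af_exac_all=afs[3],
        af_exac_eas=afs[4],
        segdup=segdup,
        inhouse_non_npc_family_count=inhouse_fam,
        inhouse_npc_individual_count=inhouse_npc,
    )
    return AnnotatedVariant(site, ann)


@pytest.fixture
def uncle_nephew_family() -> Family:
    """Six-member avuncular pedigree: affected uncle and nephew, unaffected
    connecting parent, plus unaffected grandparents."""
    fid = "AVU"
    return Family.from_members(
        fid,
        [
            make_individual("GF", fid, sex=Sex.MALE, affection=Affection.UNAFFECTED),
            make_individual("GM", fid, sex=Sex.FEMALE, affection=Affection.UNAFFECTED),
            make_individual(
                "UNCLE", fid, "GF", "GM", Sex.MALE, Affection.AFFECTED
            ),
            make_individual(
                "PARENT", fid, "GF", "GM", Sex.FEMALE, Affection.UNAFFECTED
            ),
            make_individual("SPOUSE", fid, sex=Sex.MALE, affection=Affection.UNAFFECTED),
            make_individual(
                "NEPHEW", fid, "SPOUSE", "PARENT", Sex.MALE, Affection.AFFECTED
            ),
        ],
    )


@pytest.fixture
def cousin_family() -> Family:
    """Pedigree with an affected first-cousin pair linked through siblings."""
    fid = "COUS"
    return Family.from_members(
        fid,
        [
            make_individual("GF", fid, sex=Sex.MALE),
            make_individual("GM", fid, sex=Sex.FEMALE),
            make_individual(
                "P1", fid, "GF", "GM", Sex.MALE, Affection.UNAFFECTED, sequenced=False
            ),
            make_individual(
                "P2", fid, "GF", "GM", Sex.FEMALE, Affection.UNAFFECTED, sequenced=False
            ),
            make_individual("S1", fid, sex=Sex.FEMALE),
            make_individual("S2", fid, sex=Sex.MALE),
            make_individual("C1", fid, "P1", "S1", Sex.MALE, Affection.AFFECTED),
            make_individual("C2", fid, "S2", "P2", Sex.FEMALE, Affection.AFFECTED),
            make_individual("C3", fid, "P1", "S1", Sex.FEMALE, Affection.UNAFFECTED),
        ],
    )


@pytest.fixture(scope="session")
def sim_cohort(tmp_path_factory):
    """One default synthetic cohort shared by the slower integration tests."""
    from famseg.synthetic import SimulationConfig, simulate_cohort

    out = tmp_path_factory.mktemp("cohort")
    return simulate_cohort(SimulationConfig(seed=11), out)
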