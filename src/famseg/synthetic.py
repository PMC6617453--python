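"""Truth-labeled synthetic cohorts for the family-based rare-variant analysis.

The generator emits a complete input bundle — PED pedigrees, a
multi-sample VCF, the annotation TSV, a GMT gene-set file, a serum panel,
and a truth table — mirroring the structure of a multiplex-family exome
study: by default 97 families (35 of qualifying configuration A, i.e.
3+ affected or 2 affected plus an obligate carrier, and 62 families split
between configurations B and C), 13 planted causal variants in 12 genes,
and one distractor variant per filter rule or segregation-failure mode.

Planted causal variants follow dominant transmission in their supporting
families: carried by every sequenced affected member and obligate
carrier, absent from unaffected blood relatives, population frequencies
at or below 0.5%, CADD >= 15, a retained functional class, and clean
depth.  Each distractor is identical except for exactly one violated
property, including a phenocopy (absent from one affected member) and a
variant co-segregating in only a single sibling-pair family.

The serum panel draws case/control magnesium values from group-specific
normal distributions (defaults 1.9 and 2.1 mg/dL) with deficiency
status assigned by Bernoulli draws (defaults 7.1% and 1.7%) and values
placed on the matching side of the deficiency threshold (0.7 mmol/L).

All randomness flows through one seeded generator; identical seeds give
byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .biomarker import MGDL_PER_MMOLL
from .pedigree import Affection, Family, Individual, Sex

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "DISTRACTOR_CLASSES",
    "DISTRACTOR_EXPECTED_RULE",
    "generate_pedigrees",
    "generate_variant_data",
    "generate_serum_panel",
    "generate_gene_sets",
    "simulate_cohort",
]

#: distractor catalogue: one per hard-filter rule plus two segregation modes
DISTRACTOR_CLASSES = (
    "depth",
    "segdup",
    "frequency",
    "inhouse_families",
    "inhouse_npc",
    "synonymous",
    "cadd",
    "phenocopy",
    "single_c_family",
)

#: where each distractor is expected to fall: a filter rule name, or the
#: segregation stage for variants that pass every hard filter
DISTRACTOR_EXPECTED_RULE = {
    "depth": "depth",
    "segdup": "segdup",
    "frequency": "frequency",
    "inhouse_families": "inhouse",
    "inhouse_npc": "inhouse",
    "synonymous": "functional",
    "cadd": "cadd",
    "phenocopy": "segregation",
    "single_c_family": "segregation",
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_families_a: int = 35
    n_families_b: int = 31
    n_families_c: int = 31
    n_families_uninformative: int = 0
    n_planted: int = 13
    n_planted_genes: int = 12
    distractor_classes: tuple[str, ...] = DISTRACTOR_CLASSES
    missingness: float = 0.02
    depth_mean: float = 60.0
    depth_sd: float = 12.0
    min_clean_depth: int = 12
    # serum panel
    n_cases: int = 197
    n_controls: int = 237
    p_deficient_cases: float = 0.071
    p_deficient_controls: float = 0.017
    mean_cases_mgdl: float = 1.9
    mean_controls_mgdl: float = 2.1
    sd_mgdl: float = 0.25
    threshold_mmoll: float = 0.7

    def __post_init__(self) -> None:
        for name in ("missingness", "p_deficient_cases", "p_deficient_controls"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_families_a", "n_families_b", "n_families_c",
            "n_families_uninformative", "n_planted", "n_cases", "n_controls",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_planted and not 0 < self.n_planted_genes <= self.n_planted:
            raise ValueError("need 0 < n_planted_genes <= n_planted")
        unknown = set(self.distractor_classes) - set(DISTRACTOR_CLASSES)
        if unknown:
            raise ValueError(f"unknown distractor classes: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# Pedigree templates


def _ind(fid, iid, pat, mat, sex, affection, sequenced, obligate=False):
    return Individual(
        person_id=iid, family_id=fid,
        father_id=pat, mother_id=mat, sex=sex,
        affection=affection, sequenced=sequenced, declared_obligate=obligate,
    )


def _family_trio3(fid: str) -> tuple[list[Individual], list[str]]:
    """Configuration A via three affected sequenced siblings."""
    m = [
        _ind(fid, f"{fid}_F", None, None, Sex.MALE, Affection.UNKNOWN, False),
        _ind(fid, f"{fid}_M", None, None, Sex.FEMALE, Affection.UNKNOWN, False),
    ]
    carriers = []
    for k in (1, 2, 3):
        iid = f"{fid}_A{k}"
        m.append(_ind(fid, iid, f"{fid}_F", f"{fid}_M", Sex.MALE if k % 2 else Sex.FEMALE,
                      Affection.AFFECTED, True))
        carriers.append(iid)
    return m, carriers


def _family_obligate(fid: str) -> tuple[list[Individual], list[str]]:
    """Configuration A via two affected plus a structurally obligate carrier."""
    gf, gm = f"{fid}_GF", f"{fid}_GM"
    p, ps, c = f"{fid}_P", f"{fid}_PS", f"{fid}_C"
    members = [
        _ind(fid, gf, None, None, Sex.MALE, Affection.AFFECTED, True),
        _ind(fid, gm, None, None, Sex.FEMALE, Affection.UNKNOWN, False),
        _ind(fid, p, gf, gm, Sex.MALE, Affection.UNAFFECTED, True, obligate=True),
        _ind(fid, ps, None, None, Sex.FEMALE, Affection.UNKNOWN, False),
        _ind(fid, c, p, ps, Sex.MALE, Affection.AFFECTED, True),
    ]
    return members, [gf, p, c]


def _family_avuncular(fid: str) -> tuple[list[Individual], list[str]]:
    """Configuration B: affected uncle and nephew plus a sequenced unaffected sibling."""
    gf, gm = f"{fid}_GF", f"{fid}_GM"
    u, p, ps = f"{fid}_U", f"{fid}_P", f"{fid}_PS"
    n, n2 = f"{fid}_N", f"{fid}_N2"
    members = [
        _ind(fid, gf, None, None, Sex.MALE, Affection.UNKNOWN, False),
        _ind(fid, gm, None, None, Sex.FEMALE, Affection.UNKNOWN, False),
        _ind(fid, u, gf, gm, Sex.MALE, Affection.AFFECTED, True),
        _ind(fid, p, gf, gm, Sex.FEMALE, Affection.UNAFFECTED, False),
        _ind(fid, ps, None, None, Sex.MALE, Affection.UNKNOWN, False),
        _ind(fid, n, ps, p, Sex.MALE, Affection.AFFECTED, True),
        _ind(fid, n2, ps, p, Sex.FEMALE, Affection.UNAFFECTED, True),
    ]
    return members, [u, n]


def _family_sibpair(fid: str) -> tuple[list[Individual], list[str]]:
    """Configuration C: an affected sequenced sibling pair."""
    f, m = f"{fid}_F", f"{fid}_M"
    c1, c2 = f"{fid}_A1", f"{fid}_A2"
    members = [
        _ind(fid, f, None, None, Sex.MALE, Affection.UNKNOWN, False),
        _ind(fid, m, None, None, Sex.FEMALE, Affection.UNKNOWN, False),
        _ind(fid, c1, f, m, Sex.MALE, Affection.AFFECTED, True),
        _ind(fid, c2, f, m, Sex.FEMALE, Affection.AFFECTED, True),
    ]
    return members, [c1, c2]


def _family_uninformative(fid: str) -> tuple[list[Individual], list[str]]:
    members = [
        _ind(fid, f"{fid}_F", None, None, Sex.MALE, Affection.AFFECTED, True),
        _ind(fid, f"{fid}_M", None, None, Sex.FEMALE, Affection.UNAFFECTED, True),
    ]
    return members, [f"{fid}_F"]


@dataclass
class _FamilyPlan:
    family: Family
    kind: str  # "A", "B", "C", "uninformative"
    carriers: list[str]  # members het for a variant supported by this family


def _plan_families(config: SimulationConfig) -> list[_FamilyPlan]:
    plans: list[_FamilyPlan] = []
    for i in range(config.n_families_a):
        fid = f"FA{i + 1:03d}"
        builder = _family_trio3 if i % 2 == 0 else _family_obligate
        members, carriers = builder(fid)
        plans.append(_FamilyPlan(Family.from_members(fid, members), "A", carriers))
    for i in range(config.n_families_b):
        fid = f"FB{i + 1:03d}"
        members, carriers = _family_avuncular(fid)
        plans.append(_FamilyPlan(Family.from_members(fid, members), "B", carriers))
    for i in range(config.n_families_c):
        fid = f"FC{i + 1:03d}"
        members, carriers = _family_sibpair(fid)
        plans.append(_FamilyPlan(Family.from_members(fid, members), "C", carriers))
    for i in range(config.n_families_uninformative):
        fid = f"FU{i + 1:03d}"
        members, carriers = _family_uninformative(fid)
        plans.append(
            _FamilyPlan(Family.from_members(fid, members), "uninformative", carriers)
        )
    return plans


_SEX_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_PHENO_CODE = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}


def _render_ped(plans: list[_FamilyPlan]) -> str:
    lines = []
    for plan in plans:
        for ind in plan.family.members.values():
            lines.append(
                "\t".join(
                    [
                        ind.family_id,
                        ind.person_id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_CODE[ind.sex],
                        _PHENO_CODE[ind.affection],
                        "1" if ind.sequenced else "0",
                        "1" if ind.declared_obligate else "0",
                    ]
                )
            )
    return "\n".join(lines) + "\n" if lines else ""


def generate_pedigrees(config: SimulationConfig) -> tuple[str, list[Family]]:
    """Build the requested family mix; returns PED text and parsed families."""
    plans = _plan_families(config)
    return _render_ped(plans), [p.family for p in plans]


# ---------------------------------------------------------------------------
# Variant planning


@dataclass
class _VariantPlan:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cadd: float
    afs: dict[str, float]
    segdup: int
    inhouse_fam: int
    inhouse_npc: int
    truth_class: str
    intended_rule: str
    supporting: list[str]
    carriers: dict[str, list[str]] = field(default_factory=dict)  # family -> sample ids
    carrier_depth: int | None = None  # override for depth distractor


def _clean_afs(rng: np.random.Generator) -> dict[str, float]:
    keys = ("AF_1KG_ALL", "AF_1KG_EAS", "AF_ESP6500", "AF_EXAC_ALL", "AF_EXAC_EAS")
    return {
        k: float(round(rng.uniform(0.0, 0.004), 6)) if rng.random() < 0.5 else 0.0
        for k in keys
    }


def _plan_variants(
    config: SimulationConfig, plans: list[_FamilyPlan], rng: np.random.Generator
) -> list[_VariantPlan]:
    by_kind = {
        kind: [p for p in plans if p.kind == kind] for kind in ("A", "B", "C")
    }
    counters = {"A": 0, "B": 0, "C": 0}

    def next_family(kind: str) -> _FamilyPlan:
        pool = by_kind[kind]
        if not pool:
            raise ValueError(f"no configuration-{kind} family available for placement")
        plan = pool[counters[kind] % len(pool)]
        counters[kind] += 1
        return plan

    variants: list[_VariantPlan] = []
    pos = 100_000
    planted_genes = [f"PGENE{j + 1:03d}" for j in range(config.n_planted_genes)]
    bases = ["A", "C", "G", "T"]

    for i in range(config.n_planted):
        gene = planted_genes[i % config.n_planted_genes]
        rule = ("rule1", "rule2", "rule3")[i % 3]
        if rule == "rule1":
            supporting = [next_family("A")]
        elif rule == "rule2":
            supporting = [next_family("B")]
        else:
            supporting = [next_family("C"), next_family("C")]
        consequence = "nonsynonymous"
        ref = bases[i % 4]
        alt = bases[(i + 1) % 4]
        if i == 4:
            consequence = "splicing"
        elif i == 7:
            consequence = "inframe_indel"
            ref, alt = "TACAACA", "T"  # 6-bp in-frame deletion, already normalized
        elif i == 10:
            consequence = "nonsense"
        if i == 0:
            # boundary-value variant: exactly at every retention threshold
            cadd = 15.0
            afs = {k: 0.005 for k in
                   ("AF_1KG_ALL", "AF_1KG_EAS", "AF_ESP6500", "AF_EXAC_ALL", "AF_EXAC_EAS")}
            inhouse_fam, inhouse_npc = 3, 50
        else:
            cadd = float(round(rng.uniform(15.0, 40.0), 3))
            afs = _clean_afs(rng)
            inhouse_fam = int(rng.integers(0, 4))
            inhouse_npc = int(rng.integers(0, 51))
        variants.append(
            _VariantPlan(
                chrom="1", pos=pos, ref=ref, alt=alt, gene=gene,
                consequence=consequence, cadd=cadd, afs=afs, segdup=0,
                inhouse_fam=inhouse_fam, inhouse_npc=inhouse_npc,
                truth_class="planted_causal", intended_rule=rule,
                supporting=[p.family.family_id for p in supporting],
                carriers={p.family.family_id: list(p.carriers) for p in supporting},
            )
        )
        pos += 1_000

    for k, cls in enumerate(config.distractor_classes):
        gene = f"DGENE{k + 1:02d}"
        cadd = float(round(rng.uniform(16.0, 35.0), 3))
        afs = _clean_afs(rng)
        consequence = "nonsynonymous"
        segdup = 0
        inhouse_fam = int(rng.integers(0, 4))
        inhouse_npc = int(rng.integers(0, 51))
        carrier_depth = None
        if cls == "single_c_family":
            supporting = [next_family("C")]
        else:
            supporting = [next_family("A")]
        carriers = {p.family.family_id: list(p.carriers) for p in supporting}
        if cls == "depth":
            carrier_depth = 5
        elif cls == "segdup":
            segdup = 1
        elif cls == "frequency":
            afs = dict(afs, AF_EXAC_EAS=0.006)
        elif cls == "inhouse_families":
            inhouse_fam = 4
        elif cls == "inhouse_npc":
            inhouse_npc = 51
        elif cls == "synonymous":
            consequence = "synonymous"
        elif cls == "cadd":
            cadd = 8.943
        elif cls == "phenocopy":
            # present in all but one affected member of its family
            fid = supporting[0].family.family_id
            carriers[fid] = carriers[fid][1:]
        variants.append(
            _VariantPlan(
                chrom="1", pos=pos, ref="G", alt="A", gene=gene,
                consequence=consequence, cadd=cadd, afs=afs, segdup=segdup,
                inhouse_fam=inhouse_fam, inhouse_npc=inhouse_npc,
                truth_class=f"distractor:{cls}", intended_rule="none",
                supporting=[p.family.family_id for p in supporting],
                carriers=carriers, carrier_depth=carrier_depth,
            )
        )
        pos += 1_000
    return variants


# ---------------------------------------------------------------------------
# Rendering


def _render_vcf(
    variants: list[_VariantPlan],
    samples: list[str],
    sample_family: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> str:
    header = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    lines = list(header)
    for plan in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        carrier_ids = {s for fam_carriers in plan.carriers.values() for s in fam_carriers}
        depths = np.clip(
            np.rint(rng.normal(config.depth_mean, config.depth_sd, size=len(samples))),
            config.min_clean_depth,
            None,
        ).astype(int)
        missing_draw = rng.random(len(samples))
        cells = []
        for j, sample in enumerate(samples):
            depth = int(depths[j])
            if sample in carrier_ids:
                if plan.carrier_depth is not None:
                    depth = plan.carrier_depth
                cells.append(f"0/1:{depth}")
            elif sample_family[sample] in plan.carriers:
                # non-carrier member of a supporting family: keep a clean call
                cells.append(f"0/0:{depth}")
            elif missing_draw[j] < config.missingness:
                cells.append(f"./.:{depth}")
            else:
                cells.append(f"0/0:{depth}")
        lines.append(
            f"{plan.chrom}\t{plan.pos}\t.\t{plan.ref}\t{plan.alt}\t.\tPASS\t.\tGT:DP\t"
            + "\t".join(cells)
        )
    return "\n".join(lines) + "\n"


def _render_annotations(variants: list[_VariantPlan]) -> str:
    header = (
        "CHROM\tPOS\tREF\tALT\tGENE\tCONSEQUENCE\tCADD_PHRED\tAF_1KG_ALL\t"
        "AF_1KG_EAS\tAF_ESP6500\tAF_EXAC_ALL\tAF_EXAC_EAS\tSEGDUP\t"
        "INHOUSE_NONNPC_FAM\tINHOUSE_NPC_IND"
    )
    lines = [header]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        afs = v.afs
        lines.append(
            "\t".join(
                [
                    v.chrom, str(v.pos), v.ref, v.alt, v.gene, v.consequence,
                    f"{v.cadd:g}",
                    f"{afs['AF_1KG_ALL']:g}", f"{afs['AF_1KG_EAS']:g}",
                    f"{afs['AF_ESP6500']:g}", f"{afs['AF_EXAC_ALL']:g}",
                    f"{afs['AF_EXAC_EAS']:g}",
                    str(v.segdup), str(v.inhouse_fam), str(v.inhouse_npc),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def _truth_frame(variants: list[_VariantPlan]) -> pd.DataFrame:
    rows = [
        {
            "CHROM": v.chrom,
            "POS": v.pos,
            "REF": v.ref,
            "ALT": v.alt,
            "GENE": v.gene,
            "CLASS": v.truth_class,
            "INTENDED_RULE": v.intended_rule,
            "EXPECTED_FAILURE": (
                ""
                if v.truth_class == "planted_causal"
                else DISTRACTOR_EXPECTED_RULE[v.truth_class.split(":", 1)[1]]
            ),
            "FAMILIES": ";".join(v.supporting),
        }
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    ]
    return pd.DataFrame(rows)


def generate_variant_data(
    config: SimulationConfig,
    plans: list[_FamilyPlan] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, str, pd.DataFrame]:
    """VCF text, annotation TSV text, and the truth table."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if plans is None:
        plans = _plan_families(config)
    samples: list[str] = []
    sample_family: dict[str, str] = {}
    for plan in plans:
        for pid in plan.family.sequenced_ids():
            samples.append(pid)
            sample_family[pid] = plan.family.family_id
    variants = _plan_variants(config, plans, rng)
    vcf_text = _render_vcf(variants, samples, sample_family, config, rng)
    ann_text = _render_annotations(variants)
    return vcf_text, ann_text, _truth_frame(variants)


# ---------------------------------------------------------------------------
# Serum panel and gene sets


def generate_serum_panel(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Case/control serum magnesium panel (mg/dL) with planted deficiency rates."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    threshold = round(config.threshold_mmoll * MGDL_PER_MMOLL, 4)
    floor_def = math.floor(threshold * 1000 - 1) / 1000  # strictly below threshold
    ceil_ok = math.ceil(threshold * 1000) / 1000
    rows = []
    for group, n, p_def, mean in (
        ("case", config.n_cases, config.p_deficient_cases, config.mean_cases_mgdl),
        ("control", config.n_controls, config.p_deficient_controls, config.mean_controls_mgdl),
    ):
        deficient = rng.random(n) < p_def
        sd = config.sd_mgdl
        values = np.empty(n)
        n_def = int(deficient.sum())
        if n_def:
            b = (threshold - mean) / sd
            values[deficient] = truncnorm.rvs(
                -10.0, b, loc=mean, scale=sd, size=n_def, random_state=rng
            )
        if n - n_def:
            a = (threshold - mean) / sd
            values[~deficient] = truncnorm.rvs(
                a, 10.0, loc=mean, scale=sd, size=n - n_def, random_state=rng
            )
        values = np.round(values, 3)
        values[deficient] = np.minimum(values[deficient], floor_def)
        values[~deficient] = np.maximum(values[~deficient], ceil_ok)
        prefix = "CASE" if group == "case" else "CTRL"
        for i, v in enumerate(values):
            rows.append(
                {
                    "SUBJECT": f"{prefix}{i + 1:04d}",
                    "GROUP": group,
                    "MG": round(float(v), 3),
                    "VALUE_UNIT": "mg/dL",
                    "THRESHOLD": threshold,
                }
            )
    return pd.DataFrame(rows, columns=["SUBJECT", "GROUP", "MG", "VALUE_UNIT", "THRESHOLD"])


def _serum_text(panel: pd.DataFrame) -> str:
    lines = ["\t".join(panel.columns)]
    for row in panel.itertuples(index=False):
        lines.append(
            f"{row.SUBJECT}\t{row.GROUP}\t{row.MG:.3f}\t{row.VALUE_UNIT}\t{row.THRESHOLD:.4f}"
        )
    return "\n".join(lines) + "\n"


def generate_gene_sets(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
    pathway_size: int = 38,
    n_overlap: int = 6,
) -> str:
    """GMT text: one pathway enriched for planted genes plus filler sets."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    planted = sorted(set(truth.loc[truth["CLASS"] == "planted_causal", "GENE"]))
    overlap = planted[:n_overlap]
    fillers = [f"FGENE{j + 1:04d}" for j in range(200)]
    enriched = overlap + fillers[: max(0, pathway_size - len(overlap))]
    lines = ["PATHWAY_PLANTED\tsynthetic enriched pathway\t" + "\t".join(enriched)]
    offset = pathway_size
    for s in range(3):
        size = 20 + 10 * s
        members = fillers[offset : offset + size]
        offset += size
        lines.append(f"PATHWAY_NULL{s + 1}\tsynthetic filler pathway\t" + "\t".join(members))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    out_dir: Path
    ped: Path
    vcf: Path
    annotations: Path
    truth_table: Path
    serum: Path
    gene_sets: Path
    truth: pd.DataFrame


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> SimulatedCohort:
    """Write the full synthetic input bundle into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    plans = _plan_families(config)
    ped_text = _render_ped(plans)
    vcf_text, ann_text, truth = generate_variant_data(config, plans, rng)
    serum = generate_serum_panel(config, rng)
    gmt_text = generate_gene_sets(config, truth, rng)

    paths = {
        "ped": out_dir / "families.ped",
        "vcf": out_dir / "data.vcf",
        "annotations": out_dir / "annotations.tsv",
        "truth_table": out_dir / "truth.tsv",
        "serum": out_dir / "serum.tsv",
        "gene_sets": out_dir / "sets.gmt",
    }
    paths["ped"].write_text(ped_text)
    paths["vcf"].write_text(vcf_text)
    paths["annotations"].write_text(ann_text)
    truth.to_csv(paths["truth_table"], sep="\t", index=False)
    paths["serum"].write_text(_serum_text(serum))
    paths["gene_sets"].write_text(gmt_text)
    return SimulatedCohort(
        config=config, out_dir=out_dir, truth=truth, **paths
    )
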