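"""Pedigree parsing, relationship classification, and obligate-carrier inference.

A multiplex family is represented as a directed acyclic graph of
parent -> child edges.  Under a dominant single-founder transmission model,
an *obligate carrier* is an unaffected individual who must carry the
family's variant in every transmission configuration that is consistent
with (i) the variant entering the family through exactly one founder,
(ii) transmission occurring only from parent to child, and (iii) every
affected member carrying the variant.

Families are classified into three qualifying configurations used by the
cross-family co-segregation rules:

* ``A`` — at least 3 sequenced affected members, or at least 2 sequenced
  affected members plus a sequenced obligate carrier;
* ``B`` — at least 2 sequenced affected members, of which some pair is
  neither siblings nor a parent-child pair, plus at least one sequenced
  unaffected blood relative;
* ``C`` — at least 2 sequenced affected members, all pairs being siblings
  or parent-child pairs.

Anything else is uninformative for the dominant-model analysis.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "Sex",
    "Affection",
    "RelationshipClass",
    "FamilyConfiguration",
    "Individual",
    "Family",
    "PedigreeError",
    "NonSegregatingPedigreeError",
    "read_ped",
    "classify_relationship",
    "infer_obligate_carriers",
    "classify_family_configuration",
    "resolve_obligate_carriers",
]


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, missing parent, duplicate id)."""


class NonSegregatingPedigreeError(PedigreeError):
    """No single-founder dominant transmission explains the affected members."""

    def __init__(self, family_id: str, pair: tuple[str, str]):
        self.family_id = family_id
        self.pair = pair
        super().__init__(
            f"family {family_id}: affected individuals {pair[0]!r} and {pair[1]!r} "
            "share no founder lineage under single-founder dominant transmission"
        )


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class RelationshipClass(enum.Enum):
    SIBLING = "sibling"
    PARENT_CHILD = "parent_child"
    OTHER = "other"


class FamilyConfiguration(enum.Enum):
    A = "A"
    B = "B"
    C = "C"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class Individual:
    person_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    sequenced: bool = True
    declared_obligate: bool = False

    def __post_init__(self) -> None:
        if self.declared_obligate and self.affection is not Affection.UNAFFECTED:
            raise PedigreeError(
                f"{self.person_id}: declared obligate carriers must be unaffected"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Family:
    """A pedigree: members indexed by person id plus the parent->child graph."""

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)
    _graph: nx.DiGraph = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    @classmethod
    def from_members(cls, family_id: str, members: Iterable[Individual]) -> "Family":
        index: dict[str, Individual] = {}
        for ind in members:
            if ind.person_id in index:
                raise PedigreeError(
                    f"family {family_id}: duplicate person id {ind.person_id!r}"
                )
            index[ind.person_id] = ind
        fam = cls(family_id=family_id, members=index)
        fam.validate()
        return fam

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            for parent_id, expected_sex in (
                (ind.father_id, Sex.MALE),
                (ind.mother_id, Sex.FEMALE),
            ):
                if parent_id is None:
                    continue
                if parent_id not in self.members:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {parent_id!r} of "
                        f"{ind.person_id!r} is not a member"
                    )
                parent = self.members[parent_id]
                if parent.sex not in (expected_sex, Sex.UNKNOWN):
                    raise PedigreeError(
                        f"family {self.family_id}: parent {parent_id!r} of "
                        f"{ind.person_id!r} has incompatible sex"
                    )
                g.add_edge(parent_id, ind.person_id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise PedigreeError(
                f"family {self.family_id}: cycle in parentage involving "
                f"{cycle[0][0]!r}"
            )
        self._graph = g

    @property
    def graph(self) -> nx.DiGraph:
        if self._graph is None:
            self.validate()
        return self._graph

    def founders(self) -> list[str]:
        return [pid for pid, ind in self.members.items() if ind.is_founder]

    def affected(self) -> list[str]:
        return [
            pid
            for pid, ind in self.members.items()
            if ind.affection is Affection.AFFECTED
        ]

    def sequenced_ids(self) -> list[str]:
        return [pid for pid, ind in self.members.items() if ind.sequenced]

    def _reaches(self, source: str, target: str, *, excluding: str | None = None) -> bool:
        """Parent->child reachability (source reaches itself)."""
        if source == target:
            return excluding != source
        if excluding in (source, target):
            return False
        g = self.graph
        if excluding is None:
            return nx.has_path(g, source, target)
        sub = nx.restricted_view(g, [excluding], [])
        return nx.has_path(sub, source, target)

    def feasible_source_founders(self) -> list[str]:
        """Founders from which every affected member is reachable by descent."""
        affected = self.affected()
        return [
            f
            for f in self.founders()
            if all(self._reaches(f, a) for a in affected)
        ]

    def blood_relatives(self) -> set[str]:
        """Members related by descent to the family's affected lineage.

        Non-founders are always blood relatives.  A founder is a blood
        relative when it is a feasible single source for all affected
        members; when no founder reaches every affected member (or the
        family has no affected members) any founder with an affected
        descendant counts, and with no affected members at all every
        founder does.  Married-in spouses whose only link to the affected
        core is through their own children are thereby excluded in the
        informative configurations.
        """
        blood = {pid for pid, ind in self.members.items() if not ind.is_founder}
        affected = self.affected()
        if not affected:
            return set(self.members)
        feasible = self.feasible_source_founders()
        if feasible:
            blood.update(feasible)
        else:
            blood.update(
                f
                for f in self.founders()
                if any(self._reaches(f, a) for a in affected)
            )
        blood.update(affected)
        return blood


# ---------------------------------------------------------------------------
# PED input


_PHENO = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED,
          "0": Affection.UNKNOWN, "-9": Affection.UNKNOWN}
_SEX = {"1": Sex.MALE, "2": Sex.FEMALE}


def read_ped(path: str | Path) -> list[Family]:
    """Read a whitespace-delimited PED file into validated families.

    Columns: FID IID PAT MAT SEX PHENO [SEQUENCED] [OBLIGATE].  ``0`` in
    PAT/MAT marks a founder; phenotype coding is 1 = unaffected,
    2 = affected, 0/-9 = unknown.  The optional boolean columns default to
    sequenced = true and declared obligate = false.
    """
    rows: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}: line {lineno}: expected >=6 PED columns, got {len(fields)}"
                )
            fid, iid, pat, mat, sex, pheno = fields[:6]
            sequenced = fields[6] == "1" if len(fields) > 6 else True
            obligate = fields[7] == "1" if len(fields) > 7 else False
            if pheno not in _PHENO:
                raise PedigreeError(
                    f"{path}: line {lineno}: unrecognized phenotype code {pheno!r}"
                )
            ind = Individual(
                person_id=iid,
                family_id=fid,
                father_id=None if pat == "0" else pat,
                mother_id=None if mat == "0" else mat,
                sex=_SEX.get(sex, Sex.UNKNOWN),
                affection=_PHENO[pheno],
                sequenced=sequenced,
                declared_obligate=obligate,
            )
            rows.setdefault(fid, []).append(ind)
    return [Family.from_members(fid, members) for fid, members in rows.items()]


# ---------------------------------------------------------------------------
# Relationship classification


def classify_relationship(family: Family, a: str, b: str) -> RelationshipClass:
    """Classify the pair as sibling, parent_child, or other.

    Full siblings require both recorded parents to match; half-siblings and
    any more distant relationship (grandparental, avuncular, cousins, ...)
    classify as ``other``.
    """
    if a == b:
        raise ValueError("relationship requires two distinct individuals")
    try:
        ia, ib = family.members[a], family.members[b]
    except KeyError as exc:
        raise LookupError(
            f"family {family.family_id}: unknown person id {exc.args[0]!r}"
        ) from None
    if b in (ia.father_id, ia.mother_id) or a in (ib.father_id, ib.mother_id):
        return RelationshipClass.PARENT_CHILD
    if (
        ia.father_id is not None
        and ia.mother_id is not None
        and ia.father_id == ib.father_id
        and ia.mother_id == ib.mother_id
    ):
        return RelationshipClass.SIBLING
    return RelationshipClass.OTHER


# ---------------------------------------------------------------------------
# Obligate-carrier inference


def infer_obligate_carriers(family: Family) -> set[str]:
    """Unaffected members that carry under every consistent transmission.

    For each feasible source founder (a founder from which every affected
    member descends) the necessary carriers are the members whose removal
    disconnects some affected member from the source, i.e. the dominators
    of the affected set in the parent->child DAG.  The obligate carriers
    are the unaffected members necessary under *every* feasible source.
    This agrees with the brute-force enumeration of all single-founder
    carrier sets: a member avoidable for some source appears in some valid
    carrier set that excludes it, so only dominators common to all feasible
    sources are forced.
    """
    affected = family.affected()
    if len(affected) < 2:
        raise ValueError(
            f"family {family.family_id}: obligate inference requires >=2 affected members"
        )
    feasible = family.feasible_source_founders()
    if not feasible:
        founders = family.founders()
        for a1, a2 in itertools.combinations(affected, 2):
            if not any(
                family._reaches(f, a1) and family._reaches(f, a2) for f in founders
            ):
                raise NonSegregatingPedigreeError(family.family_id, (a1, a2))
        # all pairs pairwise compatible, but no founder covers everyone
        raise NonSegregatingPedigreeError(family.family_id, (affected[0], affected[-1]))

    necessary_per_source: list[set[str]] = []
    for f in feasible:
        necessary = set()
        for x in family.members:
            if x == f:
                necessary.add(x)
                continue
            if any(not family._reaches(f, a, excluding=x) for a in affected):
                necessary.add(x)
        necessary_per_source.append(necessary)

    forced = set.intersection(*necessary_per_source)
    return {
        pid
        for pid in forced
        if family.members[pid].affection is Affection.UNAFFECTED
    }


def resolve_obligate_carriers(family: Family) -> set[str]:
    """Declared obligate carriers plus inferred ones where inference applies.

    Inference is attempted only for families with >=2 affected members; a
    non-segregating pedigree contributes no inferred carriers (the family
    is simply uninformative for the dominant model).
    """
    obligates = {
        pid for pid, ind in family.members.items() if ind.declared_obligate
    }
    if len(family.affected()) >= 2:
        try:
            obligates |= infer_obligate_carriers(family)
        except NonSegregatingPedigreeError:
            pass
    return obligates


# ---------------------------------------------------------------------------
# Family configuration


def classify_family_configuration(
    family: Family, obligates: set[str] | None = None
) -> FamilyConfiguration:
    """Classify a family into qualifying configuration A, B, C or uninformative.

    Members of unknown affection are ignored.  The unaffected blood
    relative required by configuration B excludes married-in relatives.
    """
    if obligates is None:
        obligates = resolve_obligate_carriers(family)
    aff_seq = [
        pid
        for pid, ind in family.members.items()
        if ind.sequenced and ind.affection is Affection.AFFECTED
    ]
    oblig_seq = [
        pid for pid in obligates if family.members[pid].sequenced
    ]
    if len(aff_seq) >= 3 or (len(aff_seq) >= 2 and oblig_seq):
        return FamilyConfiguration.A
    if len(aff_seq) >= 2:
        pairs = [
            classify_relationship(family, a, b)
            for a, b in itertools.combinations(sorted(aff_seq), 2)
        ]
        blood = family.blood_relatives()
        unaffected_blood_seq = [
            pid
            for pid, ind in family.members.items()
            if ind.sequenced
            and ind.affection is Affection.UNAFFECTED
            and pid in blood
        ]
        if any(p is RelationshipClass.OTHER for p in pairs) and unaffected_blood_seq:
            return FamilyConfiguration.B
        if all(
            p in (RelationshipClass.SIBLING, RelationshipClass.PARENT_CHILD)
            for p in pairs
        ):
            return FamilyConfiguration.C
    return FamilyConfiguration.UNINFORMATIVE
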