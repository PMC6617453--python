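"""Independent brute-force oracles used only by the test suite.

These deliberately take the slow, enumerative route so they share no code
path with the implementations they check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

from famseg.pedigree import (
    Affection,
    Family,
    Individual,
    NonSegregatingPedigreeError,
    Sex,
)


def enumerate_obligate_carriers(family: Family) -> set[str]:
    """Brute-force single-founder dominant-transmission enumeration.

    A carrier set S is consistent when it contains every affected member,
    exactly one founder (the entry point), and every other member of S
    has a parent in S.  The obligate carriers are the unaffected members
    present in every consistent S.
    """
    members = sorted(family.members)
    affected = [m for m in members if family.members[m].affection is Affection.AFFECTED]
    founders = {m for m in members if family.members[m].is_founder}
    valid: list[set[str]] = []
    for mask in range(1, 1 << len(members)):
        subset = {m for i, m in enumerate(members) if mask >> i & 1}
        if not all(a in subset for a in affected):
            continue
        entry = subset & founders
        if len(entry) != 1:
            continue
        (source,) = entry
        ok = True
        for m in subset:
            if m == source:
                continue
            ind = family.members[m]
            if ind.father_id not in subset and ind.mother_id not in subset:
                ok = False
                break
        if ok:
            valid.append(subset)
    if not valid:
        raise NonSegregatingPedigreeError(family.family_id, (affected[0], affected[-1]))
    forced = set.intersection(*valid)
    return {
        m for m in forced if family.members[m].affection is Affection.UNAFFECTED
    }


def random_pedigree(
    rng: np.random.Generator,
    family_id: str = "RND",
    max_members: int = 12,
    p_affected: float = 0.35,
    p_consanguineous: float = 0.1,
) -> Family:
    """Random acyclic pedigree with >=2 affected members.

    Grown from one founder couple by repeatedly adding children, marrying
    in founder spouses, or (rarely) pairing two existing blood members, so
    the parent graph is a DAG but not necessarily a tree.
    """
    n_target = int(rng.integers(4, max_members + 1))
    sexes = {"I1": Sex.MALE, "I2": Sex.FEMALE}
    parents: dict[str, tuple[str | None, str | None]] = {"I1": (None, None), "I2": (None, None)}
    couples: list[tuple[str, str]] = [("I1", "I2")]
    counter = 3
    while len(parents) < n_target:
        roll = rng.random()
        if roll < p_consanguineous and len(parents) >= 4:
            males = [p for p, s in sexes.items() if s is Sex.MALE]
            females = [p for p, s in sexes.items() if s is Sex.FEMALE]
            pair = (males[rng.integers(len(males))], females[rng.integers(len(females))])
            if pair not in couples:
                couples.append(pair)
            continue
        if roll < 0.45 and len(parents) + 1 < n_target:
            # marry in a new founder spouse for a random member
            partner = sorted(parents)[rng.integers(len(parents))]
            spouse = f"I{counter}"
            counter += 1
            sexes[spouse] = Sex.FEMALE if sexes[partner] is Sex.MALE else Sex.MALE
            parents[spouse] = (None, None)
            pair = (
                (partner, spouse) if sexes[partner] is Sex.MALE else (spouse, partner)
            )
            if pair not in couples:
                couples.append(pair)
            continue
        father, mother = couples[rng.integers(len(couples))]
        child = f"I{counter}"
        counter += 1
        sexes[child] = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        parents[child] = (father, mother)

    ids = sorted(parents)
    # affection concentrates in the original founder lineage (married-in
    # spouses are only rarely affected, to also exercise the
    # non-segregating error path)
    lineage = {"I1", "I2"}
    changed = True
    while changed:
        changed = False
        for pid, (fa, mo) in parents.items():
            if pid not in lineage and (fa in lineage or mo in lineage):
                lineage.add(pid)
                changed = True
    affection = {}
    for _ in range(50):
        affection = {
            pid: (
                Affection.AFFECTED
                if rng.random() < (p_affected if pid in lineage else 0.05)
                else Affection.UNAFFECTED
            )
            for pid in ids
        }
        if sum(a is Affection.AFFECTED for a in affection.values()) >= 2:
            break
    else:  # pragma: no cover - vanishingly unlikely
        affection = {pid: Affection.AFFECTED for pid in ids}
    members = [
        Individual(
            person_id=pid,
            family_id=family_id,
            father_id=parents[pid][0],
            mother_id=parents[pid][1],
            sex=sexes[pid],
            affection=affection[pid],
            sequenced=True,
        )
        for pid in ids
    ]
    return Family.from_members(family_id, members)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by explicit enumeration, conditioning on columns.

    Table probabilities are proportional to C(c1, j) * C(c0, r1 - j) with
    margins fixed (the complementary conditioning to the implementation's
    row-wise form), with exact rational tie comparison.
    """
    r1, c1, c0 = a + b, a + c, b + d
    n = a + b + c + d
    lo, hi = max(0, r1 - c0), min(r1, c1)
    weights = {j: comb(c1, j) * comb(c0, r1 - j) for j in range(lo, hi + 1)}
    observed = weights[a]
    total = Fraction(
        sum(w for w in weights.values() if w <= observed), comb(n, r1)
    )
    return float(min(Fraction(1), total))


def hypergeom_tail_exact(k: int, K: int, n: int, M: int) -> float:
    """Exact right tail via integer combinatorics (Fraction arithmetic)."""
    numerator = sum(comb(K, j) * comb(M - K, n - j) for j in range(k, min(K, n) + 1))
    return float(Fraction(numerator, comb(M, n)))
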