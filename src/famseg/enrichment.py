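"""Gene-set over-representation of a candidate gene list.

The test is the standard one-sided (right-tail) hypergeometric: with a
reference universe of M genes, a pathway of K genes, and a candidate list
of n genes, the p-value for an observed overlap of k genes is
P(X >= k) for X ~ Hypergeometric(M, K, n), accumulated in log space.
Gene symbols are matched case-insensitively, with no alias resolution.
The universe size defaults to 23,000 protein-coding genes and is a
configuration value, because curated pathway knowledge bases rarely
publish their reference set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Iterable, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

import pandas as pd

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "GmtParseError",
    "read_gmt",
    "hypergeom_tail",
    "enrich_pathways",
    "results_to_frame",
]


class GmtParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise GmtParseError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentResult:
    pathway: str
    n_overlap: int
    n_pathway: int
    n_candidates: int
    universe_size: int
    p_value: float
    overlap_genes: list[str]
    bh_q: float | None = None

    @property
    def ratio(self) -> str:
        """Overlap ratio in the ``k/K (percent%)`` display convention."""
        pct = round(100 * self.n_overlap / self.n_pathway)
        return f"{self.n_overlap}/{self.n_pathway} ({pct}%)"


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file: name, description, then tab-separated member genes."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected name, description and at "
                    f"least one member gene, got {len(fields)} fields"
                )
            name, description = fields[0], fields[1]
            members = frozenset(g.strip().upper() for g in fields[2:] if g.strip())
            if not members:
                raise GmtParseError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, members=members, description=description))
    return sets


def hypergeom_tail(k: int, K: int, n: int, M: int) -> float:
    """Right tail P(X >= k) for X ~ Hypergeometric(M, K, n), in log space."""
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValueError(f"infeasible counts: K={K}, n={n}, M={M}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    lo = max(k, K + n - M)
    support = np.arange(lo, min(K, n) + 1)
    log_tail = logsumexp(hypergeom.logpmf(support, M, K, n))
    return float(min(1.0, np.exp(log_tail)))


def enrich_pathways(
    candidate_genes: Iterable[str],
    gene_sets: Sequence[GeneSet],
    universe: int | Collection[str] = 23000,
) -> list[EnrichmentResult]:
    """One-sided over-representation of the candidates against each gene set.

    ``universe`` may be an explicit gene collection (membership is then
    enforced and candidate genes outside it are an error) or just its
    size.  Results come back sorted by ascending p-value with
    Benjamini-Hochberg q-values attached.
    """
    candidates = sorted({g.strip().upper() for g in candidate_genes if g.strip()})
    if isinstance(universe, int):
        universe_size = universe
        universe_set: frozenset[str] | None = None
    else:
        universe_set = frozenset(g.strip().upper() for g in universe)
        universe_size = len(universe_set)
        offenders = [g for g in candidates if g not in universe_set]
        if offenders:
            raise ValueError(
                f"candidate genes outside the universe: {', '.join(offenders)}"
            )
    if len(candidates) > universe_size:
        raise ValueError("candidate list larger than the universe")
    candidate_set = set(candidates)
    results: list[EnrichmentResult] = []
    for gene_set in gene_sets:
        members = gene_set.members
        if universe_set is not None:
            members = frozenset(members & universe_set)
        overlap = sorted(candidate_set & members)
        K = len(members)
        p = hypergeom_tail(len(overlap), K, len(candidates), universe_size) if K else 1.0
        results.append(
            EnrichmentResult(
                pathway=gene_set.name,
                n_overlap=len(overlap),
                n_pathway=K,
                n_candidates=len(candidates),
                universe_size=universe_size,
                p_value=p,
                overlap_genes=overlap,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.pathway))
    if results:
        q_values = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for result, q in zip(results, q_values):
            result.bh_q = float(q)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "pathway": r.pathway,
            "k": r.n_overlap,
            "K": r.n_pathway,
            "ratio": r.ratio,
            "percent": round(100 * r.n_overlap / r.n_pathway) if r.n_pathway else 0,
            "p": r.p_value,
            "bh_q": r.bh_q,
            "overlap_genes": ",".join(r.overlap_genes),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["pathway", "k", "K", "ratio", "percent", "p", "bh_q", "overlap_genes"]
    )
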