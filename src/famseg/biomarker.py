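"""Serum-magnesium case-control statistics.

Deficiency is a strict threshold call (serum magnesium below an
instrument-specific cutoff, typically 0.7 or 0.78 mmol/L); cases and
controls form a 2x2 contingency table analysed with

* the cross-product odds ratio and Woolf's log-scale 95% confidence
  interval (variance 1/a + 1/b + 1/c + 1/d), with the Haldane-Anscombe
  0.5 correction when a cell is empty;
* the two-sided Fisher exact test under the minimum-likelihood convention
  (sum over tables with the observed margins whose probability does not
  exceed the observed table's), computed in exact integer arithmetic;
* a Pearson chi-square companion statistic (optional Yates correction).

Group-level comparisons use the Wilcoxon rank-sum test by default (exact
when both groups have at most 20 tie-free observations), with Welch's
t-test and a permutation test available, since published reports often
leave the test unstated.

Values may be recorded in mg/dL or mmol/L; conversion uses the molar mass
of magnesium: 1 mmol/L = 2.431 mg/dL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MGDL_PER_MMOLL",
    "ContingencyTable",
    "OddsRatioResult",
    "ChiSquareResult",
    "GroupComparison",
    "reconstruct_counts",
    "odds_ratio_woolf",
    "exact_test_p",
    "chi_square_p",
    "compare_group_levels",
    "deficiency_flags",
    "read_serum_panel",
    "format_estimate",
]

#: 1 mmol/L of magnesium (molar mass 24.31 g/mol) equals 2.431 mg/dL.
MGDL_PER_MMOLL = 2.431

SERUM_COLUMNS = ["SUBJECT", "GROUP", "MG", "VALUE_UNIT", "THRESHOLD"]

_CASE_LABELS = {"case", "affected"}
_CONTROL_LABELS = {"control", "unaffected"}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 deficiency table: a/b = cases, c/d = controls (deficient first)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


class OddsRatioResult(NamedTuple):
    odds_ratio: float
    ci_low: float
    ci_high: float
    corrected: bool = False


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float


class GroupComparison(NamedTuple):
    mean_a: float
    mean_b: float
    p_value: float
    method: str


def reconstruct_counts(n_group: int, proportion: float) -> int:
    """Recover an integer count from a group size and a printed proportion.

    Rounds half away from zero, so 197 x 0.071 = 13.987 -> 14 and
    237 x 0.017 = 4.029 -> 4.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError(f"proportion {proportion} outside [0, 1]")
    return int(math.floor(n_group * proportion + 0.5))


def odds_ratio_woolf(table: ContingencyTable, z: float = 1.959963984540054) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf's log-interval.

    An empty cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell), flagged in the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        raise ValueError("degenerate table: an entire margin is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsratio = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(oddsratio)
    return OddsRatioResult(
        odds_ratio=oddsratio,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        corrected=corrected,
    )


def exact_test_p(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p under the minimum-likelihood convention.

    With margins fixed, table probabilities are proportional to
    C(r1, j) * C(r0, c1 - j); ties are decided by exact integer
    comparison, so no floating-point tolerance is involved.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r0, c1 = a + b, c + d, a + c
    n = r1 + r0
    if n == 0:
        raise ValueError("empty table")
    lo, hi = max(0, c1 - r0), min(r1, c1)
    weights = [math.comb(r1, j) * math.comb(r0, c1 - j) for j in range(lo, hi + 1)]
    observed = weights[a - lo]
    numerator = sum(w for w in weights if w <= observed)
    return min(1.0, numerator / math.comb(n, c1))


def chi_square_p(table: ContingencyTable, continuity: bool = False) -> ChiSquareResult:
    """Pearson chi-square on the 2x2 table (df = 1), optional Yates correction."""
    statistic, p, _, _ = stats.chi2_contingency(
        table.as_array(), correction=continuity
    )
    return ChiSquareResult(statistic=float(statistic), p_value=float(p))


def _wilcoxon_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # zero-variance degenerate case
        return 1.0
    tie_free = len(np.unique(pooled)) == len(x) + len(y)
    if tie_free and max(len(x), len(y)) <= 20:
        method = "exact"
    else:
        # ties or large n: normal approximation, no continuity correction, so
        # a central statistic (e.g. identical groups) yields exactly p = 1
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(1.0, res.pvalue))


def compare_group_levels(
    panel: pd.DataFrame,
    method: str = "wilcoxon",
    rng: np.random.Generator | None = None,
) -> GroupComparison:
    """Two-group comparison of serum levels.

    ``panel`` needs GROUP and MG columns; groups are case/affected versus
    control/unaffected.  ``method`` is one of ``wilcoxon`` (rank-sum,
    default), ``t_test`` (Welch) or ``permutation`` (mean difference,
    10,000 resamples; pass ``rng`` for reproducibility).
    """
    groups = panel["GROUP"].astype(str).str.lower()
    x = panel.loc[groups.isin(_CASE_LABELS), "MG"].to_numpy(dtype=float)
    y = panel.loc[groups.isin(_CONTROL_LABELS), "MG"].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one measurement")
    if method == "wilcoxon":
        p = _wilcoxon_p(x, y)
    elif method == "t_test":
        p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    elif method == "permutation":
        rng = rng or np.random.default_rng(0)
        res = stats.permutation_test(
            (x, y),
            lambda u, v, axis=-1: np.mean(u, axis=axis) - np.mean(v, axis=axis),
            permutation_type="independent",
            n_resamples=10_000,
            alternative="two-sided",
            rng=rng,
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(float(np.mean(x)), float(np.mean(y)), p, method)


def _to_mmoll(value: float, unit: str) -> float:
    unit = unit.strip().lower().replace(" ", "")
    if unit in ("mmol/l", "mmoll", "mmol"):
        return value
    if unit in ("mg/dl", "mgdl", "mg"):
        return value / MGDL_PER_MMOLL
    raise ValueError(f"unknown magnesium unit {unit!r}")


def deficiency_flags(panel: pd.DataFrame) -> ContingencyTable:
    """Assemble the deficiency 2x2 table from a serum panel.

    Each row carries its own threshold in its declared unit; a subject is
    deficient when the measurement is strictly below the threshold.
    Comparisons are performed in mmol/L after unit conversion.
    """
    a = b = c = d = 0
    for row in panel.itertuples(index=False):
        value = _to_mmoll(float(row.MG), str(row.VALUE_UNIT))
        threshold = _to_mmoll(float(row.THRESHOLD), str(row.VALUE_UNIT))
        deficient = value < threshold
        group = str(row.GROUP).strip().lower()
        if group in _CASE_LABELS:
            a, b = (a + 1, b) if deficient else (a, b + 1)
        elif group in _CONTROL_LABELS:
            c, d = (c + 1, d) if deficient else (c, d + 1)
        else:
            raise ValueError(f"unknown group label {row.GROUP!r}")
    return ContingencyTable(a, b, c, d)


def read_serum_panel(path: str | Path) -> pd.DataFrame:
    """Read the serum TSV (SUBJECT GROUP MG VALUE_UNIT THRESHOLD)."""
    panel = pd.read_csv(path, sep="\t")
    missing = [c for c in SERUM_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"{path}: missing serum panel columns {missing}")
    return panel


def format_estimate(value: float) -> str:
    """Report an OR or CI bound: one decimal below 10, two significant figures above."""
    if value < 10:
        return f"{value:.1f}"
    return f"{float(f'{value:.2g}'):g}"
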