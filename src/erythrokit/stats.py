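"""Group statistics: summaries, Mann-Whitney U, Pearson r, fold changes.

Thin, explicit wrappers around scipy.stats with the conventions used
throughout the toolkit: two-sided tests, exact Mann-Whitney p-values for
small tie-free samples (normal approximation with tie and continuity
correction otherwise), and the usual significance-star coding.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats as sps

EXACT_PRODUCT_LIMIT = 400   # use exact U distribution when n*m <= this and no ties


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(self.n)


def summarize(values: np.ndarray) -> GroupSummary:
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty sample")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return GroupSummary(n=int(v.size), mean=float(np.mean(v)), sd=sd)


def mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    Exact enumeration of the U distribution when n*m <= 400 with no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("both samples need >= 3 values")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (x.size * y.size <= EXACT_PRODUCT_LIMIT and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation coefficient in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with >= 3 values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance sample")
    return float(sps.pearsonr(x, y).statistic)


def fold_change(a: GroupSummary, b: GroupSummary) -> float:
    """Ratio of group means a/b."""
    if b.mean == 0:
        raise ValueError("zero denominator group mean")
    return a.mean / b.mean


def star_code(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be within [0, 1]")
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
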