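"""Nonparametric comparison and correlation machinery.

All component comparisons in the pipeline run through these three tests:
Wilcoxon matched-pairs signed-rank for paired component data,
Mann-Whitney U for unpaired groups, and Spearman rank correlation.

Conventions (fixed for reproducible reports):

* two-sided p-values by doubling the smaller tail, capped at 1;
* signed-rank: zero differences dropped before ranking (Wilcoxon's
  original convention, not Pratt's), exact null distribution for
  n_effective <= 25 without ties, otherwise a normal approximation with
  tie and continuity correction;
* Mann-Whitney: exact for min(nA, nB) <= 8 without ties, otherwise
  normal approximation with tie correction;
* Spearman: average ranks for ties; exact permutation p for n <= 9,
  otherwise the t approximation.

The exact switchover sizes are desk-scale enumeration limits and are
exposed as keyword arguments.  No multiple-testing correction is applied
by default; :func:`benjamini_hochberg` is available when wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "spearman",
    "benjamini_hochberg",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a rank test: statistic, two-sided p and group medians."""

    statistic: float
    p_value: float
    n_effective: int
    method: str  # exact | normal_approx | permutation | t_approx | degenerate
    medians: dict = field(default_factory=dict)
    warning: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _two_sided(lower_tail: float, upper_tail: float) -> float:
    return min(1.0, 2.0 * min(lower_tail, upper_tail))


@lru_cache(maxsize=64)
def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Exact null distribution of W+ over ranks 1..n (counts, then CDF)."""
    counts = np.zeros(n * (n + 1) // 2 + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r else counts
        counts = counts + shifted
    return np.cumsum(counts) / 2.0 ** n


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]],
    exact_limit: int = 25,
) -> TestResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    The statistic is W+, the sum of ranks of positive differences a - b.
    Zero differences are dropped before ranking; if all differences are
    zero the result is degenerate with p = 1.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one pair")
    a = np.asarray([p[0] for p in pairs], dtype=float)
    b = np.asarray([p[1] for p in pairs], dtype=float)
    medians = {"a": float(np.median(a)), "b": float(np.median(b)),
               "difference": float(np.median(a - b))}
    d = (a - b)[a != b]
    n = len(d)
    if n == 0:
        return TestResult(0.0, 1.0, 0, "degenerate", medians,
                          warning="all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= exact_limit and not has_ties:
        cdf = _signed_rank_null_cdf(n)
        w = int(round(w_plus))
        lower = cdf[w]
        upper = 1.0 - (cdf[w - 1] if w > 0 else 0.0)
        return TestResult(w_plus, _two_sided(lower, upper), n, "exact",
                          medians)
    mean = n * (n + 1) / 4.0
    tie_sizes = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(
        tie_sizes ** 3 - tie_sizes) / 48.0
    if var == 0:
        return TestResult(w_plus, 1.0, n, "degenerate", medians,
                          warning="zero variance after tie correction")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, p, n, "normal_approx", medians)


@lru_cache(maxsize=256)
def _u_null_cdf(n1: int, n2: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic for sizes n1, n2.

    Built from the Gaussian-binomial recurrence
    N(u; n1, n2) = N(u - n2; n1 - 1, n2) + N(u; n1 - 1, n2 - 1)
    implemented as an iterative polynomial product.
    """
    # distribution of sum of n1 ranks drawn without replacement is
    # equivalent to coefficients of the q-binomial [n1+n2, n1]_q
    counts = np.zeros(n1 * n2 + 1)
    counts[0] = 1.0
    # multiply by (1 - q^(n2 + i)) / (1 - q^i) for i = 1..n1
    for i in range(1, n1 + 1):
        # multiply by 1/(1 - q^i): cumulative sum with stride i
        for j in range(i, len(counts)):
            counts[j] += counts[j - i]
        # multiply by (1 - q^(n2 + i))
        k = n2 + i
        if k < len(counts):
            counts[k:] -= counts[:-k].copy()
    total = counts.sum()
    return np.cumsum(counts) / total


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_limit: int = 8,
) -> TestResult:
    """Two-sided Mann-Whitney U test; statistic is U for group A."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    medians = {"a": float(np.median(a)), "b": float(np.median(b))}
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n1].sum())
    u_a = r_a - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    if min(n1, n2) <= exact_limit and not has_ties:
        cdf = _u_null_cdf(n1, n2)
        u = int(round(u_a))
        lower = cdf[u]
        upper = 1.0 - (cdf[u - 1] if u > 0 else 0.0)
        return TestResult(u_a, _two_sided(lower, upper), n1 + n2, "exact",
                          medians)
    mean = n1 * n2 / 2.0
    n = n1 + n2
    tie_sizes = np.unique(pooled, return_counts=True)[1]
    var = (n1 * n2 / 12.0) * (
        (n + 1) - np.sum(tie_sizes ** 3 - tie_sizes) / (n * (n - 1)))
    if var == 0:
        return TestResult(u_a, 1.0, n, "degenerate", medians,
                          warning="all pooled values identical")
    z = (u_a - mean - 0.5 * np.sign(u_a - mean)) / math.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u_a, p, n, "normal_approx", medians)


def _rank_corr(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc) / denom


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact_limit: int = 9,
) -> TestResult:
    """Spearman rank correlation with average ranks for ties.

    p-value by full permutation enumeration for n <= ``exact_limit``,
    otherwise the t approximation.  A constant input vector yields an
    undefined (NaN) rho with a warning rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(float("nan"), 1.0, n, "degenerate", {},
                          warning="constant input vector: rho undefined")
    xr = sps.rankdata(x)
    yr = sps.rankdata(y)
    rho = _rank_corr(xr, yr)
    if n <= exact_limit:
        perms = np.array(list(permutations(range(n))))
        xc = xr - xr.mean()
        yc = yr - yr.mean()
        denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
        rhos = (yc[perms] @ xc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return TestResult(rho, p, n, "permutation", {})
    if abs(rho) >= 1.0:
        return TestResult(rho, 0.0, n, "t_approx", {})
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = min(1.0, 2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(rho, p, n, "t_approx", {})


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH-adjusted q-values (optional; reports default to unadjusted p)."""
    from statsmodels.stats.multitest import multipletests

    return list(multipletests(p_values, method="fdr_bh")[1])
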