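"""Nonparametric tests with exact small-sample nulls.

All group comparisons in this pipeline use rank-based tests: the Wilcoxon
rank-sum test for pairwise comparisons, the Wilcoxon signed-rank test for
paired designs (e.g. pre/post toxin current densities), the Kruskal–Wallis
test across three or more groups, and the F-test of a simple linear
regression for correlation claims.

For small samples the null distribution is computed exactly by complete
enumeration — every assignment of observations to groups (rank-sum,
C(n+m, n) splits), every sign pattern (signed-rank, 2**n patterns), every
partition of the pooled ranks (Kruskal–Wallis) — so that p-values are exact
multiples of 1/#outcomes.  Enumeration is used only on tie-free data below a
size cutoff; otherwise a normal (or chi-squared) approximation with midrank
tie correction is used and flagged as such in the result.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "rank_sum",
    "signed_rank",
    "kruskal_wallis",
    "pearson_regression",
    "RegressionResult",
]

# exact-enumeration cutoffs: C(16, 8) = 12 870 splits, 2**20 sign patterns
RANK_SUM_EXACT_MAX_N = 16
SIGNED_RANK_EXACT_MAX_N = 20
KRUSKAL_EXACT_MAX_N = 10


@dataclass
class TestResult:
    """Outcome of one hypothesis test.

    ``exact`` is True only when the p-value came from complete enumeration
    of the permutation null; ``n_per_group`` records the design size.
    """

    method: str
    statistic: float
    p_value: float
    sided: str
    exact: bool
    n_per_group: tuple

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return sps.rankdata(pooled, method="average")


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def _two_sided_from_one(p_one: float) -> float:
    return min(1.0, 2.0 * p_one)


def rank_sum(x: Sequence[float], y: Sequence[float], sided: str = "two") -> TestResult:
    """Wilcoxon rank-sum (Mann–Whitney) test of two independent samples.

    The statistic is the sum of midranks of ``x`` in the pooled sample.
    Exact p by enumeration of all C(n+m, n) group assignments when
    n+m <= 16 and the pooled data are tie-free; otherwise a normal
    approximation with tie and continuity correction.

    One-sided alternative: ``x`` tends larger than ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w = float(ranks[:n].sum())

    if n + m <= RANK_SUM_EXACT_MAX_N and not _has_ties(pooled):
        # enumerate every choice of n positions for the x-sample
        all_ranks = np.arange(1, n + m + 1)
        sums = np.array(
            [sum(c) for c in itertools.combinations(all_ranks, n)], dtype=float
        )
        total = sums.size
        mu = n * (n + m + 1) / 2.0
        if sided == "one":
            p = float(np.count_nonzero(sums >= w)) / total
        else:
            tail = min(
                np.count_nonzero(sums >= w), np.count_nonzero(sums <= w)
            ) / total
            p = _two_sided_from_one(tail)
        return TestResult("wilcoxon_rank_sum", w, max(p, 1.0 / total), sided, True, (n, m))

    # normal approximation with tie correction
    mu = n * (n + m + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    nm = n + m
    var = n * m / 12.0 * ((nm + 1) - tie_term / (nm * (nm - 1.0)))
    if var <= 0:
        return TestResult("wilcoxon_rank_sum", w, 1.0, sided, False, (n, m))
    z = (w - mu - 0.5 * np.sign(w - mu)) / math.sqrt(var)  # continuity corrected
    if sided == "one":
        p = float(sps.norm.sf(z))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult("wilcoxon_rank_sum", w, min(max(p, np.finfo(float).tiny), 1.0), sided, False, (n, m))


def signed_rank(pre: Sequence[float], post: Sequence[float], sided: str = "two") -> TestResult:
    """Wilcoxon signed-rank test on paired data.

    Differences ``post - pre``; zero differences are dropped (Wilcoxon
    convention).  Statistic is W+, the sum of ranks of positive
    differences.  Exact p by enumeration of 2**n sign patterns for
    n <= 20; otherwise normal approximation with tie correction.

    One-sided alternative: ``post`` tends larger than ``pre``.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.size < 2:
        raise ValueError("pre and post must be equal-length with >= 2 pairs")
    if sided not in ("two", "one"):
        raise ValueError("sided must be 'two' or 'one'")
    d = post - pre
    d = d[d != 0.0]
    if d.size == 0:
        raise ValueError("all differences are zero: test degenerate")
    n = d.size
    abs_ranks = sps.rankdata(np.abs(d), method="average")
    w_plus = float(abs_ranks[d > 0].sum())

    if n <= SIGNED_RANK_EXACT_MAX_N and not _has_ties(np.abs(d)):
        # all 2**n sign patterns, vectorized over blocks of bits
        signs = np.array(
            list(itertools.product([0.0, 1.0], repeat=n)), dtype=float
        )
        sums = signs @ abs_ranks
        total = sums.size
        if sided == "one":
            p = float(np.count_nonzero(sums >= w_plus)) / total
        else:
            tail = min(
                np.count_nonzero(sums >= w_plus), np.count_nonzero(sums <= w_plus)
            ) / total
            p = _two_sided_from_one(tail)
        return TestResult("wilcoxon_signed_rank", w_plus, max(p, 1.0 / total), sided, True, (n,))

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var)
    if sided == "one":
        p = float(sps.norm.sf(z))
    else:
        p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult("wilcoxon_signed_rank", w_plus, min(max(p, np.finfo(float).tiny), 1.0), sided, False, (n,))


def _kw_h(groups_ranks, n_total, tie_term):
    h = 0.0
    for r in groups_ranks:
        h += r.sum() ** 2 / r.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    return h / correction if correction > 0 else 0.0


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test over two or more independent groups.

    Midrank H statistic with tie correction; chi-squared p with k-1
    degrees of freedom, or exact enumeration of all rank partitions when
    the total sample size is at most 10 and the data are tie-free.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    sizes = tuple(g.size for g in groups)
    n_total = sum(sizes)
    if n_total < 3:
        raise ValueError("need a total of at least 3 observations")
    pooled = np.concatenate(groups)
    ranks = _midranks(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    splits = np.split(ranks, np.cumsum(sizes)[:-1])
    h = _kw_h(splits, n_total, tie_term)

    if n_total <= KRUSKAL_EXACT_MAX_N and not _has_ties(pooled):
        # enumerate every partition of ranks 1..N into groups of the given sizes
        all_ranks = frozenset(range(1, n_total + 1))

        def partitions(remaining, size_list):
            if not size_list:
                yield []
                return
            k = size_list[0]
            for combo in itertools.combinations(sorted(remaining), k):
                for rest in partitions(remaining - set(combo), size_list[1:]):
                    yield [np.array(combo, dtype=float)] + rest

        hs = np.array(
            [_kw_h(p, n_total, 0.0) for p in partitions(all_ranks, list(sizes))]
        )
        total = hs.size
        p = float(np.count_nonzero(hs >= h - 1e-12)) / total
        return TestResult("kruskal_wallis", h, max(p, 1.0 / total), "two", True, sizes)

    p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return TestResult("kruskal_wallis", h, min(max(p, np.finfo(float).tiny), 1.0), "two", False, sizes)


@dataclass
class RegressionResult:
    r: float
    slope: float
    intercept: float
    f_statistic: float
    p_value: float
    n: int
    p_is_bound: bool = False


def pearson_regression(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Pearson product-moment correlation with the regression F-test.

    Ordinary least-squares line y = a + b x; F = (n-2) r^2 / (1 - r^2)
    on (1, n-2) degrees of freedom.  On perfectly collinear data F is
    reported as +inf and the p-value as the machine-floor bound.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise ValueError("need n >= 3 paired observations")
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    if sxx == 0.0 or syy == 0.0:
        raise ValueError("zero variance in x or y")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    r = sxy / math.sqrt(sxx * syy)
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if abs(r) >= 1.0 - 1e-15:
        return RegressionResult(r, slope, intercept, math.inf,
                                np.finfo(float).tiny, n, p_is_bound=True)
    f = (n - 2) * r**2 / (1.0 - r**2)
    p = float(sps.f.sf(f, 1, n - 2))
    return RegressionResult(r, slope, intercept, f,
                            min(max(p, np.finfo(float).tiny), 1.0), n)
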