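"""Exact small-sample nonparametric tests.

The study designs this package serves have 3-8 samples per group, where
asymptotic rank-test p-values are unreliable; signed-rank and rank-sum
p-values are therefore computed exactly (distribution-counting recurrence over
the observed mid-rank multiset, so ties are handled by enumeration of the
actual tie structure) for up to 25 observations, with a continuity-corrected
normal approximation beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 25


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    sided: str
    exact: bool
    degenerate: bool = False


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _sum_distribution(ranks2: np.ndarray) -> np.ndarray:
    """counts[s] of sign assignments with positive-part rank sum s, over doubled
    (integer) mid-ranks; total mass 2^n."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        new = counts.copy()
        new[r:] += counts[: total + 1 - r]
        counts = new
    return counts


def wilcoxon_signed_rank(diffs, sided: str = "two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired differences.

    Zeros are removed first; if nothing remains the result is degenerate with
    p = 1.  Statistic is W+ (sum of ranks of positive differences).  Exact
    enumeration of all 2^n sign assignments (via the counting recurrence) for
    n <= 25; normal approximation with continuity correction above that.
    sided: "greater" (positive shift), "less", or "two-sided".
    """
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("signed-rank V", 0.0, 1.0, sided, exact=True, degenerate=True)
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    total = float(ranks.sum())
    if n <= EXACT_MAX_N:
        ranks2 = np.round(ranks * 2).astype(np.int64)
        counts = _sum_distribution(ranks2)
        denom = counts.sum()
        w2 = int(round(w_plus * 2))
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
        exact = True
    else:
        mu = total / 2
        sd = np.sqrt(float((ranks**2).sum()) / 4)  # sum r_i^2 / 4 handles ties
        p_ge = float(sps.norm.sf((w_plus - 0.5 - mu) / sd))
        p_le = float(sps.norm.cdf((w_plus + 0.5 - mu) / sd))
        exact = False
    if sided == "greater":
        p = p_ge
    elif sided == "less":
        p = p_le
    elif sided == "two-sided":
        p = min(1.0, 2 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return TestResult("signed-rank V", w_plus, float(p), sided, exact)


def _ranksum_distribution(ranks2: np.ndarray, m: int) -> np.ndarray:
    """counts[s] of m-subsets of the doubled rank multiset with sum s."""
    total = int(ranks2.sum())
    dp = np.zeros((m + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        for k in range(m, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[m]


def wilcoxon_rank_sum(group_a, group_b, sided: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Statistic is W = rank sum of group A in the pooled mid-ranking.  Exact
    enumeration over all C(nA+nB, nA) assignments for nA+nB <= 25; normal
    approximation with tie correction and continuity correction otherwise.
    sided "greater" means A tends larger than B.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w = float(ranks[: len(a)].sum())
    n, m = len(pooled), len(a)
    if n <= EXACT_MAX_N:
        ranks2 = np.round(ranks * 2).astype(np.int64)
        counts = _ranksum_distribution(ranks2, m)
        denom = counts.sum()
        w2 = int(round(w * 2))
        p_ge = counts[w2:].sum() / denom
        p_le = counts[: w2 + 1].sum() / denom
        exact = True
    else:
        mu = m * (n + 1) / 2
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_corr = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = m * (n - m) / 12 * ((n + 1) - tie_corr)
        sd = np.sqrt(var)
        p_ge = float(sps.norm.sf((w - 0.5 - mu) / sd))
        p_le = float(sps.norm.cdf((w + 0.5 - mu) / sd))
        exact = False
    if sided == "greater":
        p = p_ge
    elif sided == "less":
        p = p_le
    elif sided == "two-sided":
        p = min(1.0, 2 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    degenerate = bool(np.all(pooled == pooled[0]))
    return TestResult("rank-sum W", w, float(min(p, 1.0)), sided, exact, degenerate)


def ks_two_sample(a, b) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, D = sup |ECDF_a - ECDF_b| with the
    asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return TestResult("KS D", float(res.statistic), float(res.pvalue), "two-sided", exact=False)
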