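"""Two-sided Wilcoxon rank-sum test with an exact small-sample path.

For groups of at most 12 observations each the p value is computed exactly
by enumerating the permutation distribution of the rank sum (midranks for
ties) with a generating-function convolution; larger samples use the
normal approximation with tie and continuity corrections.  The two-sided
exact p value is the probability, under random group assignment, of a rank
sum at least as far from its mean as the observed one — the distribution
of the midrank sum is symmetric about n1*(N+1)/2.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 12


def _exact_rank_sum_p(ranks2: np.ndarray, n1: int) -> float:
    """Exact two-sided p for the rank sum of group 1 (ranks doubled to ints).

    DP over subset size and doubled-rank sum: count[k][s] = number of
    k-subsets of the pooled doubled ranks with sum s.
    """
    total = int(ranks2.sum())
    n = ranks2.size
    obs = int(ranks2[:n1].sum())
    mu2 = n1 * (n + 1)            # mean of the doubled-rank sum
    # counts as float64: C(24,12) ~ 2.7e6, well within exact float range
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        dp[1:, r:] += dp[:-1, : total + 1 - r]
    counts = dp[n1]
    n_total = math.comb(n, n1)
    dev = abs(obs - mu2)
    sums = np.arange(total + 1)
    extreme = counts[np.abs(sums - mu2) >= dev - 1e-9].sum()
    return min(1.0, float(extreme / n_total))


def _asymptotic_rank_sum_p(ranks: np.ndarray, n1: int, n2: int) -> float:
    """Normal approximation with tie correction and continuity correction."""
    n = n1 + n2
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return min(1.0, 2.0 * sps.norm.sf(z))


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test of two samples.

    Returns (U statistic of the first sample, p value).  Exact enumeration
    when both groups have at most 12 observations, otherwise the corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if np.ptp(pooled) == 0:
        return u1, 1.0
    if max(n1, n2) <= EXACT_MAX_N:
        ranks2 = np.rint(2.0 * ranks).astype(int)   # midranks doubled are integers
        p = _exact_rank_sum_p(ranks2, n1)
    else:
        p = _asymptotic_rank_sum_p(ranks, n1, n2)
    return u1, p


def bonferroni(p_raw, n_tested: int) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * n_tested)."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * n_tested)
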