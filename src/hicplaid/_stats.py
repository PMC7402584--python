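"""Shared statistical primitives.

The Wilcoxon rank-sum test used for boundary significance is exact (full
enumeration of the permutation null on the observed pooled ranks, so ties
are handled correctly) whenever both samples are small, and falls back to
the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["rank_sum_p", "EXACT_MAX_N"]

# Each group at most this size -> exact enumeration (C(16, 8) = 12870 subsets).
EXACT_MAX_N = 8


def _exact_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float, alternative: str) -> float:
    """P-value by enumerating every assignment of pooled ranks to group x."""
    idx = range(len(ranks))
    sums = np.array([ranks[list(c)].sum() for c in combinations(idx, n_x)])
    total = len(sums)
    eps = 1e-9
    if alternative == "less":
        return float(np.sum(sums <= w_obs + eps) / total)
    if alternative == "greater":
        return float(np.sum(sums >= w_obs - eps) / total)
    lo = np.sum(sums <= w_obs + eps) / total
    hi = np.sum(sums >= w_obs - eps) / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def _normal_rank_sum_p(ranks: np.ndarray, n_x: int, w_obs: float, alternative: str) -> float:
    n = len(ranks)
    n_y = n - n_x
    mu = n_x * (n + 1) / 2.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n_x * n_y / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / np.sqrt(var)
    if alternative == "less":
        return float(stats.norm.cdf(z))
    if alternative == "greater":
        return float(stats.norm.sf(z))
    return float(2.0 * stats.norm.sf(abs(z)))


def rank_sum_p(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value for samples ``x`` vs ``y``.

    ``alternative='less'`` tests that values in ``x`` are stochastically
    smaller than values in ``y``. Exact when both groups have at most
    :data:`EXACT_MAX_N` observations, normal approximation otherwise.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_p requires non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w_obs = float(ranks[: x.size].sum())
    if x.size <= EXACT_MAX_N and y.size <= EXACT_MAX_N:
        return _exact_rank_sum_p(ranks, x.size, w_obs, alternative)
    return _normal_rank_sum_p(ranks, x.size, w_obs, alternative)
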