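"""Shared statistical primitives.

Thin, opinionated wrappers around scipy so that every module in the package
uses identical conventions: two-sided Wilcoxon rank-sum with an exact
small-sample path, upper-tail hypergeometric probabilities, Kendall tau-b
with an exact path, equal-weight harmonic mean p-values, and a two-sample
KS test on binned frequency vectors.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

#: largest group size for which the exact Wilcoxon null distribution is used
EXACT_GROUP_MAX = 8


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses exact enumeration of the null distribution when the smaller group
    has at most ``EXACT_GROUP_MAX`` observations and the pooled sample is
    tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty for the rank-sum test")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:
        return 1.0  # all observations identical: no evidence of a shift
    no_ties = np.unique(pooled).size == pooled.size
    if min(x.size, y.size) <= EXACT_GROUP_MAX and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    p = float(res.pvalue)
    if np.isnan(p):
        return 1.0
    return min(p, 1.0)


def wilcoxon_rank_sum_matrix(x, y) -> np.ndarray:
    """Column-wise two-sided Wilcoxon rank-sum p-values.

    ``x`` (n1 x K) and ``y`` (n2 x K) hold the two groups' values on K
    coordinates.  When the smaller group exceeds ``EXACT_GROUP_MAX`` the
    whole matrix is handed to scipy in one vectorized asymptotic call;
    otherwise each column goes through :func:`wilcoxon_rank_sum` so that
    tie-free small-sample columns get the exact p-value.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] == 0 or y.shape[0] == 0:
        raise ValueError("both groups must be nonempty for the rank-sum test")
    if x.shape[1] != y.shape[1]:
        raise ValueError("group matrices must agree on the number of columns")
    if min(x.shape[0], y.shape[0]) > EXACT_GROUP_MAX:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=True,
                                     axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        # zero-variance columns yield nan under the normal approximation
        p[np.isnan(p)] = 1.0
        return np.minimum(p, 1.0)
    return np.array([wilcoxon_rank_sum(x[:, j], y[:, j])
                     for j in range(x.shape[1])])


def hypergeom_upper_tail(k: int, N: int, m: int, q: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, m successes, q draws).

    This is the enrichment p-value P = sum_{j=k}^{q} C(m,j) C(N-m,q-j) / C(N,q).
    ``k = 0`` covers the whole sample space, so P = 1 exactly.
    """
    if not (0 <= m <= N):
        raise ValueError(f"need 0 <= m <= N, got m={m}, N={N}")
    if not (0 <= q <= N):
        raise ValueError(f"need 0 <= q <= N, got q={q}, N={N}")
    if k <= 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, N, m, q)))


def kendall_tau(x, y) -> tuple[float, float]:
    """Kendall tau-b and its two-sided p-value.

    Exact p when the sample is small and tie-free (scipy enumerates the
    permutation null), asymptotic tau-b otherwise.  Returns ``(nan, nan)``
    when either vector is constant (tau undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), float("nan")
    no_ties = (np.unique(x).size == x.size) and (np.unique(y).size == y.size)
    method = "exact" if (no_ties and x.size <= 33) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def harmonic_mean_p(pvals) -> float:
    """Equal-weight harmonic mean of p-values: L / sum(1/p_i).

    No asymptotic (Landau) calibration is applied; the raw harmonic mean is
    used as the combined significance summary, thresholded at 0.05 by
    callers.  Bounded by [min(p), max(p)].
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("harmonic mean of an empty p-value list is undefined")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return float(p.size / np.sum(1.0 / p))


def ks_binned_frequencies(counts_a, counts_b, n_a: int, n_b: int) -> tuple[float, float]:
    """Two-sample KS test on two binned relative-frequency vectors.

    The bins are treated as an ordered discrete axis; D is the maximum gap
    between the two empirical CDFs and the p-value comes from the asymptotic
    Kolmogorov distribution with effective size n_a*n_b/(n_a+n_b).
    """
    fa = np.asarray(counts_a, dtype=float)
    fb = np.asarray(counts_b, dtype=float)
    if fa.size != fb.size:
        raise ValueError("binned vectors must have equal length")
    if fa.sum() <= 0 or fb.sum() <= 0:
        raise ValueError("each frequency vector must have positive mass")
    cdf_a = np.cumsum(fa) / fa.sum()
    cdf_b = np.cumsum(fb) / fb.sum()
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    if d == 0.0:
        return 0.0, 1.0
    en = n_a * n_b / (n_a + n_b)
    # Stephens' small-sample adjustment to the asymptotic Kolmogorov law
    lam = (np.sqrt(en) + 0.12 + 0.11 / np.sqrt(en)) * d
    p = float(np.clip(stats.kstwobign.sf(lam), 0.0, 1.0))
    return d, p


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up q-values (adjusted p-values) for a vector of p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
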