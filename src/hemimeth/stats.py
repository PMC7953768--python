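"""Nonparametric tests used throughout the hemimethylation pipeline.

Three procedures are implemented from first principles because their exact
small-sample behaviour is what the site-calling logic depends on:

* the paired Wilcoxon signed-rank test (forward vs reverse strand
  methylation levels across samples at one CpG),
* the Wilcoxon rank-sum (Mann-Whitney) test (cluster-length comparisons),
* the pooled two-proportion z-test (cohort-level proportion comparisons).

Exact null distributions are computed by generating-function convolution
over the observed (possibly tied, average) rank vector, so exact p-values
remain valid under ties.  Two-sided exact p-values follow the doubled-tail
convention ``min(1, 2*min(P(T <= t), P(T >= t)))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "SignedRankResult",
    "RankSumResult",
    "TwoProportionResult",
    "signed_rank_test",
    "rank_sum_test",
    "two_proportion_test",
    "bh_adjust",
]


@dataclass(frozen=True)
class SignedRankResult:
    """Outcome of a paired Wilcoxon signed-rank test.

    Attributes
    ----------
    statistic_wplus : float
        Sum of the ranks of positive differences (W+).
    n_informative : int
        Number of nonzero paired differences actually ranked.
    p_two_sided : float
        Two-sided p-value in (0, 1].
    method : str
        ``"exact"`` (enumeration of the signed-rank null) or
        ``"normal_approx"`` (tie-corrected normal with continuity correction).
    """

    statistic_wplus: float
    n_informative: int
    p_two_sided: float
    method: str


@dataclass(frozen=True)
class RankSumResult:
    """Outcome of a Wilcoxon rank-sum (Mann-Whitney) test."""

    statistic_u: float
    p_two_sided: float
    method: str


@dataclass(frozen=True)
class TwoProportionResult:
    """Outcome of a pooled two-proportion z-test (no continuity correction)."""

    z_statistic: float
    p_two_sided: float
    p1_hat: float
    p2_hat: float


def _doubled_ranks(ranks: np.ndarray) -> np.ndarray:
    # average ranks are multiples of 1/2; doubling makes them exact integers
    doubled = np.rint(2.0 * ranks).astype(np.int64)
    return doubled


def _signed_rank_null_pmf(doubled: np.ndarray) -> np.ndarray:
    """PMF of 2*W+ under the signed-rank null for a fixed (tied) rank vector.

    Convolves ``prod_r (1 + x**r) / 2**n`` over the doubled ranks; index i of
    the result is the number of sign assignments with 2*W+ == i.
    """
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in doubled:
        counts[r : top + r + 1] += counts[: top + 1]
        top += r
    return counts / counts.sum()


def signed_rank_test(differences, exact_threshold: int = 25) -> SignedRankResult:
    """Paired Wilcoxon signed-rank test on a vector of paired differences.

    Zero differences are discarded; the absolute values of the remainder are
    ranked ascending (average ranks on ties) and W+ is the rank sum of the
    positive differences.  For ``n_informative <= exact_threshold`` the
    two-sided p-value is exact over all ``2**n`` sign assignments of the
    observed rank vector; beyond that a tie-corrected normal approximation
    with continuity correction is used.  An all-zero input carries no
    evidence and yields p = 1.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise ValueError("signed_rank_test requires a nonempty difference vector")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")

    d = d[d != 0.0]
    n = int(d.size)
    if n == 0:
        return SignedRankResult(0.0, 0, 1.0, "exact")

    ranks = rankdata(np.abs(d))
    wplus = float(ranks[d > 0].sum())

    if n <= exact_threshold:
        doubled = _doubled_ranks(ranks)
        pmf = _signed_rank_null_pmf(doubled)
        w2 = int(round(2.0 * wplus))
        p_le = float(pmf[: w2 + 1].sum())
        p_ge = float(pmf[w2:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return SignedRankResult(wplus, n, p, "exact")

    mean = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups of |d|
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / 48.0)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        return SignedRankResult(wplus, n, 1.0, "normal_approx")
    delta = wplus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var) if delta != 0 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return SignedRankResult(wplus, n, p, "normal_approx")


def _rank_sum_null_pmf(n1: int, n2: int) -> np.ndarray:
    """PMF of U for group sizes (n1, n2) under the no-tie rank-sum null.

    Dynamic programming over subsets of the pooled ranks of size n1; index u
    of the result is P(U == u), with U = R1 - n1(n1+1)/2 in 0..n1*n2.
    """
    max_u = n1 * n2
    # table[k][u]: number of k-subsets of {1..m} seen so far with shifted sum u
    table = np.zeros((n1 + 1, max_u + 1), dtype=np.float64)
    table[0, 0] = 1.0
    for m in range(1, n1 + n2 + 1):
        for k in range(min(n1, m), 0, -1):
            # adding rank m as the k-th (largest) element shifts U by m - k
            shift = m - k
            if shift == 0:
                table[k, :] += table[k - 1, :]
            else:
                table[k, shift:] += table[k - 1, :-shift]
    return table[n1] / table[n1].sum()


def rank_sum_test(group_a, group_b, exact_threshold: int = 20) -> RankSumResult:
    """Wilcoxon rank-sum test that groups a and b come from one distribution.

    The statistic is the Mann-Whitney U of group a.  The p-value is exact by
    enumeration of rank subsets when ``len(a) + len(b) <= exact_threshold``
    and the pooled values are tie-free; otherwise a tie-corrected normal
    approximation with continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("rank_sum_test requires two nonempty groups")
    n1, n2 = int(a.size), int(b.size)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if n1 + n2 <= exact_threshold and not has_ties:
        pmf = _rank_sum_null_pmf(n1, n2)
        ui = int(round(u))
        p_le = float(pmf[: ui + 1].sum())
        p_ge = float(pmf[ui:].sum())
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return RankSumResult(u, p, "exact")

    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return RankSumResult(u, 1.0, "normal_approx")
    delta = u - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var) if delta != 0 else 0.0
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return RankSumResult(u, p, "normal_approx")


def two_proportion_test(
    successes_1: int, total_1: int, successes_2: int, total_2: int
) -> TwoProportionResult:
    """Pooled two-proportion z-test without continuity correction.

    z = (p1 - p2) / sqrt(p*(1-p*)(1/n1 + 1/n2)) with p* the pooled
    proportion; the two-sided p-value is 2*(1 - Phi(|z|)).
    """
    for s, t in ((successes_1, total_1), (successes_2, total_2)):
        if t <= 0:
            raise ValueError("totals must be positive")
        if not 0 <= s <= t:
            raise ValueError("successes must lie in [0, total]")
    p1 = successes_1 / total_1
    p2 = successes_2 / total_2
    pooled = (successes_1 + successes_2) / (total_1 + total_2)
    var = pooled * (1.0 - pooled) * (1.0 / total_1 + 1.0 / total_2)
    if var == 0.0 or p1 == p2:
        z = 0.0
    else:
        z = (p1 - p2) / np.sqrt(var)
    p = 1.0 if z == 0.0 else min(1.0, 2.0 * float(norm.sf(abs(z))))
    return TwoProportionResult(float(z), p, p1, p2)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (plumbing; off by default)."""
    from scipy.stats import false_discovery_control

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return false_discovery_control(p, method="bh")
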