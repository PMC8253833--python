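"""Statistical primitives shared by every pipeline stage.

Each test returns a :class:`TestResult` recording the statistic, the
two-sided p-value and the method used, so downstream tables can always say
which test produced a number.  The rank-sum test switches to exact
enumeration of all group labelings for small samples (combined n <= 12 by
default), where the normal approximation is unreliable; the exact path
handles ties through midranks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps


class Method(str, Enum):
    wilcoxon_rank_sum = "wilcoxon_rank_sum"
    welch_t = "welch_t"
    student_t = "student_t"
    hypergeometric = "hypergeometric"


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: Method

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


class UndefinedCorrelationError(ValueError):
    """Raised when a Pearson correlation is requested on a constant vector."""


class DegenerateVarianceError(ValueError):
    """Raised when a t test is requested on groups with no variance."""


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length vectors.

    Raises :class:`UndefinedCorrelationError` if either vector is constant;
    the caller decides whether to drop the pair or propagate NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    # guard against rounding just past the boundary
    return min(1.0, max(-1.0, r))


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups."""
    _, counts = np.unique(values, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t**3 - t))


def wilcoxon_rank_sum(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two_sided",
    exact_max_n: int = 12,
) -> TestResult:
    """Unpaired two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    For combined sample size <= ``exact_max_n`` the p-value is computed by
    enumerating every assignment of the pooled observations to the two
    groups (exact under ties, via midranks):
    p = min(1, 2 * min(P(W <= w), P(W >= w))) where W is the rank sum of
    group ``a``.  Larger samples use the normal approximation with midrank
    tie correction and a 0.5 continuity correction.
    """
    if alternative != "two_sided":
        raise ValueError("only the two-sided alternative is supported")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    w_obs = float(ranks[:n1].sum())

    if n1 + n2 <= exact_max_n:
        p = _exact_rank_sum_p(ranks, n1, w_obs)
        return TestResult(statistic=w_obs, p_value=p, method=Method.wilcoxon_rank_sum)

    p = _normal_rank_sum_p(ranks, n1, n2, w_obs)
    return TestResult(statistic=w_obs, p_value=p, method=Method.wilcoxon_rank_sum)


def _exact_rank_sum_p(ranks: np.ndarray, n1: int, w_obs: float) -> float:
    n = ranks.size
    total = 0
    le = 0
    ge = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n), n1):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def _normal_rank_sum_p(ranks: np.ndarray, n1: int, n2: int, w_obs: float) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    tie = _tie_term(ranks)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var <= 0:  # all observations identical
        return 1.0
    diff = w_obs - mu
    # continuity correction shrinks |diff| by 0.5
    z = (abs(diff) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def rank_sum_matrix(a: np.ndarray, b: np.ndarray, exact_max_n: int = 12) -> np.ndarray:
    """Row-wise rank-sum p-values for two genes x cells blocks.

    Applies :func:`wilcoxon_rank_sum` semantics independently to each row;
    used by the marker cascade where thousands of genes are tested.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise ValueError("row counts differ between groups")
    n1, n2 = a.shape[1], b.shape[1]
    out = np.empty(a.shape[0])
    if n1 + n2 <= exact_max_n:
        for i in range(a.shape[0]):
            out[i] = wilcoxon_rank_sum(a[i], b[i], exact_max_n=exact_max_n).p_value
        return out
    pooled = np.hstack([a, b])
    ranks = sps.rankdata(pooled, method="average", axis=1)
    w = ranks[:, :n1].sum(axis=1)
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    ties = np.array([_tie_term(row) for row in pooled])
    var = n1 * n2 / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(w - mu) - 0.5) / np.sqrt(var)
    z = np.clip(z, 0.0, None)
    p = np.minimum(1.0, 2.0 * sps.norm.sf(z))
    p[var <= 0] = 1.0
    return p


def welch_t(a: Sequence[float], b: Sequence[float], pooled: bool = False) -> TestResult:
    """Two-sided t test; Welch (unequal variance) by default.

    ``pooled=True`` gives the classical equal-variance Student's t.  Two
    groups with zero variance and equal means return p = 1 by convention;
    zero variance with unequal means raises
    :class:`DegenerateVarianceError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    method = Method.student_t if pooled else Method.welch_t
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult(statistic=0.0, p_value=1.0, method=method)
        raise DegenerateVarianceError(
            "zero variance in both groups with unequal means"
        )
    stat, p = sps.ttest_ind(a, b, equal_var=pooled)
    return TestResult(statistic=float(stat), p_value=float(p), method=method)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    q_(i) = min over j >= i of m * p_(j) / j, clipped to 1, with the
    original input order restored.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_overlap(
    universe_n: int, set_k: int, query_n: int, overlap_k: int
) -> TestResult:
    """Upper-tail hypergeometric test: P(X >= overlap_k).

    X counts members of a size-``set_k`` set among ``query_n`` draws
    without replacement from a universe of ``universe_n`` genes.
    """
    if not (0 <= set_k <= universe_n and 0 <= query_n <= universe_n):
        raise ValueError("set and query sizes must not exceed the universe")
    if overlap_k < 0 or overlap_k > min(set_k, query_n):
        raise ValueError("impossible overlap for the given sizes")
    p = float(sps.hypergeom.sf(overlap_k - 1, universe_n, set_k, query_n))
    p = min(1.0, max(0.0, p))
    return TestResult(statistic=float(overlap_k), p_value=p, method=Method.hypergeometric)


def pearson_test(x: Sequence[float], y: Sequence[float], exact_max_n: int = 0) -> tuple[float, float]:
    """Pearson r with a two-sided p-value.

    The p-value uses the t-distribution transform of r; for n <=
    ``exact_max_n`` an exact permutation p (all n! orderings of y) is
    computed instead, feasible for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = pearson(x, y)
    n = x.size
    if exact_max_n and n <= exact_max_n:
        if n > 10:
            raise ValueError("exact permutation p limited to n <= 10")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            rp = np.corrcoef(x, y[list(perm)])[0, 1]
            total += 1
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        return r, count / total
    if n < 3:
        raise ValueError("need at least three observations for the t transform")
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)
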