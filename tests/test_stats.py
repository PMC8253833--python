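"""Unit and property tests for the statistical primitives.

Exact tests are checked against independently coded brute-force oracles
(full enumeration of labelings/draws) and against scipy/statsmodels where
an established implementation exists.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as stx
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ctcflow import stats


# ---------------------------------------------------------------------------
# oracles (deliberately independent codings)
# ---------------------------------------------------------------------------

def rank_sum_enumeration_p(a, b):
    """Two-sided rank-sum p by enumerating every labeling of the pooled data."""
    pooled = list(a) + list(b)
    n1 = len(a)
    # midranks by sorting
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(ranks[:n1])
    le = ge = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        le += w <= w_obs + 1e-9
        ge += w >= w_obs - 1e-9
    return min(1.0, 2 * min(le, ge) / total)


def hypergeom_enumeration_p(N, K, n, k):
    """Upper-tail overlap p by enumerating all C(N, n) draws."""
    items = [1] * K + [0] * (N - K)
    hits = total = 0
    for combo in itertools.combinations(range(N), n):
        total += 1
        hits += sum(items[i] for i in combo) >= k
    return hits / total


def bh_stepup_reference(p):
    """Step-up definition applied literally: q_(i) = min_{j>=i} m p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order):
        q[idx] = min(min(1.0, m * p[order[j]] / (j + 1)) for j in range(pos, m))
    return q


# ---------------------------------------------------------------------------
# pearson
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "x, y, expected",
    [([1, 2, 3], [2, 4, 6], 1.0), ([1, 2, 3], [3, 2, 1], -1.0), ([1, 2, 3], [1, 3, 2], 0.5)],
)
def test_pearson_known_values(x, y, expected):
    assert stats.pearson(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_constant_vector_raises():
    with pytest.raises(stats.UndefinedCorrelationError):
        stats.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@settings(derandomize=True, max_examples=50)
@given(
    stx.lists(stx.floats(-100, 100), min_size=3, max_size=30),
    stx.floats(0.1, 10),
    stx.floats(-5, 5),
)
def test_pearson_affine_invariance_and_symmetry(x, slope, intercept):
    x = np.asarray(x)
    if np.ptp(x) == 0:
        return
    y = slope * x + intercept
    assert stats.pearson(x, y) == pytest.approx(1.0, abs=1e-9)
    rng = np.random.default_rng(0)
    z = x + rng.normal(size=x.size)
    if np.ptp(z) == 0:
        return
    assert stats.pearson(x, z) == pytest.approx(stats.pearson(z, x))
    assert abs(stats.pearson(x, z)) <= 1.0


# ---------------------------------------------------------------------------
# wilcoxon rank-sum
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([1, 2], [3, 4], 2 / 6),
        ([1, 2, 3], [4, 5, 6], 2 / 20),
        ([5, 5, 5], [5, 5, 5], 1.0),
    ],
)
def test_rank_sum_exact_hand_cases(a, b, expected):
    assert stats.wilcoxon_rank_sum(a, b).p_value == pytest.approx(expected, abs=1e-12)


def test_rank_sum_exact_equals_enumeration_all_small_sizes():
    """Exact p equals the labeling-enumeration oracle for n1+n2 <= 10, with ties."""
    rng = np.random.default_rng(42)
    for n1 in range(1, 6):
        for n2 in range(1, 6):
            if n1 + n2 > 10:
                continue
            for _ in range(3):
                a = rng.integers(0, 5, size=n1).astype(float)  # integer draws force ties
                b = rng.integers(0, 5, size=n2).astype(float)
                got = stats.wilcoxon_rank_sum(a, b).p_value
                want = rank_sum_enumeration_p(a, b)
                assert abs(got - want) < 1e-12, (a, b)


def test_rank_sum_exact_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(1)
    for _ in range(10):
        a = rng.normal(size=4)
        b = rng.normal(size=5)
        got = stats.wilcoxon_rank_sum(a, b).p_value
        want = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert got == pytest.approx(want, abs=1e-12)


def test_rank_sum_normal_approximation_reasonable():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, size=30)
    b = rng.normal(1.5, 1, size=30)
    res = stats.wilcoxon_rank_sum(a, b)
    want = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    assert res.p_value == pytest.approx(want, rel=1e-6)


def test_rank_sum_empty_group_raises():
    with pytest.raises(ValueError):
        stats.wilcoxon_rank_sum([], [1.0])


def test_rank_sum_matrix_consistent_with_scalar():
    rng = np.random.default_rng(3)
    a = rng.normal(size=(20, 15))
    b = rng.normal(size=(20, 12))
    ps = stats.rank_sum_matrix(a, b)
    for i in range(0, 20, 5):
        assert ps[i] == pytest.approx(stats.wilcoxon_rank_sum(a[i], b[i]).p_value)


# ---------------------------------------------------------------------------
# welch / student t
# ---------------------------------------------------------------------------

def test_welch_identical_groups():
    res = stats.welch_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_welch_degenerate_variance_raises():
    with pytest.raises(stats.DegenerateVarianceError):
        stats.welch_t([0, 0, 0, 0], [1, 1, 1, 1])


def test_welch_matches_textbook_formula():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 3.0, 4.0, 5.0])
    res = stats.welch_t(a, b)
    # direct formula evaluation
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    p = 2 * sps.t.sf(abs(t), df)
    assert res.statistic == pytest.approx(t, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)
    assert np.sign(res.statistic) == np.sign(a.mean() - b.mean())


def test_student_pooled_option():
    a, b = [1.0, 2.0, 3.0], [2.5, 3.5, 4.5, 5.5]
    res = stats.welch_t(a, b, pooled=True)
    want = sps.ttest_ind(a, b, equal_var=True)
    assert res.p_value == pytest.approx(want.pvalue)
    assert res.method is stats.Method.student_t


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5], [0.5]),
        ([0.005, 0.1], [0.01, 0.1]),
    ],
)
def test_bh_hand_cases(p, expected):
    assert stats.bh_fdr(p) == pytest.approx(expected, abs=1e-12)


def test_bh_out_of_range_raises():
    with pytest.raises(ValueError):
        stats.bh_fdr([0.5, 1.5])


@settings(derandomize=True, max_examples=60)
@given(stx.lists(stx.floats(0, 1), min_size=1, max_size=40))
def test_bh_matches_reference_and_statsmodels(p):
    q = stats.bh_fdr(p)
    assert np.allclose(q, bh_stepup_reference(p), atol=1e-12)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_sm, atol=1e-12)
    # pointwise >= input, <= 1, monotone in p
    assert np.all(q >= np.asarray(p) - 1e-15) and np.all(q <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "args, expected",
    [((10, 5, 4, 4), 5 / 210), ((8, 3, 4, 0), 1.0), ((4, 2, 2, 2), 1 / 6)],
)
def test_hypergeom_hand_cases(args, expected):
    assert stats.hypergeom_overlap(*args).p_value == pytest.approx(expected, abs=1e-12)


def test_hypergeom_equals_enumeration_small_universes():
    for N in (5, 8, 12):
        for K in (2, N // 2):
            for n in (2, 3):
                for k in range(0, min(K, n) + 1):
                    got = stats.hypergeom_overlap(N, K, n, k).p_value
                    want = hypergeom_enumeration_p(N, K, n, k)
                    assert got == pytest.approx(want, abs=1e-12), (N, K, n, k)


def test_hypergeom_impossible_configuration_raises():
    with pytest.raises(ValueError):
        stats.hypergeom_overlap(10, 3, 4, 5)
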