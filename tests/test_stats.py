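"""Unit and property tests for the two-group statistics."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from mantella.stats import (
    anosim,
    bray_curtis,
    bray_curtis_matrix,
    exact_u_distribution,
    mann_whitney_p_from_u,
    mann_whitney_u,
    nmds,
    permanova,
    permutation_screen,
    stress1,
)
from mantella.stats import _exact_u_counts


# ---------------------------------------------------------------------------
# Mann-Whitney


def brute_force_u_counts(n1, n2):
    """Independent oracle: enumerate all C(n1+n2, n1) rank assignments."""
    n = n1 + n2
    counts = np.zeros(n1 * n2 + 1)
    for comb in itertools.combinations(range(1, n + 1), n1):
        counts[sum(comb) - n1 * (n1 + 1) // 2] += 1
    return counts


@pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (2, 6), (4, 4), (5, 5), (3, 7)])
def test_exact_null_distribution_equals_enumeration(n1, n2):
    counts = _exact_u_counts(n1, n2)
    assert counts.sum() == math.comb(n1 + n2, n1)
    assert np.array_equal(counts, brute_force_u_counts(n1, n2))


def test_exact_p_matches_scipy_on_untied_data():
    rng = np.random.default_rng(42)
    for _ in range(10):
        x = rng.normal(size=rng.integers(3, 12))
        y = rng.normal(size=rng.integers(3, 12))
        mine = mann_whitney_u(x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, method="exact")
        assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-12)
        assert mine.U_group1 == pytest.approx(ref.statistic)


def test_three_vs_three_extreme_case():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
    assert res.U_group1 == 0
    assert res.p_two_sided == pytest.approx(2 / 20)


def test_normal_cc_with_tie_correction_matches_scipy():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 5, size=14).astype(float)
    y = rng.integers(0, 5, size=11).astype(float)
    mine = mann_whitney_u(x, y, method="normal_cc", tie_correction=True)
    ref = sps.mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
    assert mine.p_two_sided == pytest.approx(ref.pvalue, rel=1e-10)
    assert mine.tie_corrected


def test_identical_multisets_give_central_u():
    x = [1.0, 2.0, 3.0, 4.0]
    res = mann_whitney_u(x, list(x), method="normal_cc")
    assert res.U_group1 == pytest.approx(8.0)
    assert res.p_two_sided >= 0.9


def test_constant_pooled_data_warns_and_p_one():
    with pytest.warns(UserWarning):
        res = mann_whitney_u([2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.p_two_sided == 1.0


def test_exact_method_rejects_ties():
    with pytest.raises(ValueError):
        mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0], method="exact")


def test_empty_sample_rejected():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=12),
    y=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=12),
)
def test_u_conservation_and_p_range(x, y):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mann_whitney_u(x, y, method="auto")
    assert res.U_group1 + res.U_group2 == pytest.approx(len(x) * len(y))
    assert 0 < res.p_two_sided <= 1


def test_p_from_u_exact_vs_pmf():
    pmf = exact_u_distribution(4, 5)
    assert pmf.sum() == pytest.approx(1.0)
    # two-sided p at the minimum U is twice the point mass at 0
    assert mann_whitney_p_from_u(0, 4, 5, method="exact") == pytest.approx(2 * pmf[0])


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_cases():
    assert bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0
    assert bray_curtis([100, 0], [0, 100]) == 1.0
    assert bray_curtis([60, 40], [20, 80]) == pytest.approx(0.4)


def test_bray_curtis_matrix_matches_scipy():
    rng = np.random.default_rng(0)
    X = rng.gamma(2.0, size=(8, 5))
    assert np.allclose(bray_curtis_matrix(X), squareform(pdist(X, "braycurtis")))


def test_bray_curtis_errors():
    with pytest.raises(ValueError):
        bray_curtis([0, 0], [0, 0])
    with pytest.raises(ValueError):
        bray_curtis([-1, 2], [1, 2])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    x=st.lists(st.floats(0, 100), min_size=3, max_size=6),
    y=st.lists(st.floats(0, 100), min_size=3, max_size=6),
)
def test_bray_curtis_symmetric_and_bounded(x, y):
    n = min(len(x), len(y))
    x, y = np.array(x[:n]), np.array(y[:n])
    if (x + y).sum() == 0:
        return
    d = bray_curtis(x, y)
    assert d == bray_curtis(y, x)
    assert 0 <= d <= 1
    assert (d == 0) == bool(np.all(x == y))


# ---------------------------------------------------------------------------
# NMDS


def test_nmds_recovers_embeddable_configuration():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(10, 2))
    D = squareform(pdist(pts))
    res = nmds(D, k=2, n_restarts=4, seed=5)
    assert res.stress < 0.01
    assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)


def test_nmds_duplicate_samples_coincide():
    rng = np.random.default_rng(1)
    X = rng.gamma(2.0, size=(6, 4))
    X[3] = X[0]  # duplicate sample
    D = bray_curtis_matrix(X)
    res = nmds(D, k=2, n_restarts=4, seed=2)
    gap = np.linalg.norm(res.coordinates[0] - res.coordinates[3])
    spread = np.linalg.norm(res.coordinates.std(axis=0))
    assert gap < 0.05 * max(spread, 1e-9)


def test_nmds_separates_two_tight_clusters():
    n = 5
    D = np.full((2 * n, 2 * n), 0.9)
    D[:n, :n] = 0.05
    D[n:, n:] = 0.05
    np.fill_diagonal(D, 0.0)
    res = nmds(D, k=2, n_restarts=6, seed=0)
    a, b = res.coordinates[:n], res.coordinates[n:]
    axis = b.mean(axis=0) - a.mean(axis=0)
    proj_a, proj_b = a @ axis, b @ axis
    assert proj_a.max() < proj_b.min()  # linearly separable


def test_stress_invariant_under_similarity_transforms():
    rng = np.random.default_rng(9)
    pts = rng.normal(size=(7, 2))
    D = squareform(pdist(pts)) + rng.uniform(0, 0.1, size=(7, 7))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    X = nmds(D, n_restarts=2, seed=0).coordinates
    theta = 0.8
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    s0 = stress1(D, X)
    assert stress1(D, 3.7 * X @ R) == pytest.approx(s0, abs=1e-12)
    assert stress1(D, X * [1, -1]) == pytest.approx(s0, abs=1e-12)


def test_monotone_fit_matches_sklearn_isotonic():
    sklearn_isotonic = pytest.importorskip("sklearn.isotonic")
    from mantella.stats import _monotone_fit

    rng = np.random.default_rng(12)
    x = np.round(rng.uniform(0, 1, size=80), 2)  # rounded -> plenty of ties
    y = rng.normal(x, 0.3)
    mine = _monotone_fit(x, y)
    ref = sklearn_isotonic.IsotonicRegression(increasing=True).fit_transform(x, y)
    assert np.allclose(mine, ref)
    # non-decreasing along the x order
    order = np.argsort(x)
    assert (np.diff(mine[order]) >= -1e-12).all()


def test_nmds_input_validation():
    with pytest.raises(ValueError):
        nmds(np.array([[0, 1], [2, 0]]))  # asymmetric
    D = np.zeros((3, 3))
    with pytest.raises(ValueError):
        nmds(D, k=3)  # k >= n


# ---------------------------------------------------------------------------
# PERMANOVA / ANOSIM


def test_permanova_univariate_equals_classical_anova():
    rng = np.random.default_rng(11)
    for _ in range(5):
        x = rng.normal(size=15)
        labels = np.array(["a"] * 7 + ["b"] * 8)
        D = np.abs(x[:, None] - x[None, :])
        f_ref = sps.f_oneway(x[:7], x[7:]).statistic
        res = permanova(D, labels, n_permutations=9, seed=0)
        assert abs(res.pseudo_F - f_ref) < 1e-10


def test_permanova_matches_skbio():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(4)
    X = rng.gamma(2.0, size=(12, 6))
    D = bray_curtis_matrix(X)
    labels = np.array(["a"] * 6 + ["b"] * 6)
    dm = skbio_distance.DistanceMatrix(D, ids=[str(i) for i in range(12)])
    ref = skbio_distance.permanova(dm, grouping=list(labels), permutations=49)
    res = permanova(D, labels, n_permutations=49, seed=0)
    assert res.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-10)


def test_permanova_extreme_separation_minimal_p():
    # groups of 8 so a random label permutation virtually never reproduces
    # the original partition, making the minimal p attainable
    n = 8
    D = np.full((2 * n, 2 * n), 50.0)
    D[:n, :n] = 0.01
    D[n:, n:] = 0.01
    np.fill_diagonal(D, 0.0)
    labels = np.array(["a"] * n + ["b"] * n)
    res = permanova(D, labels, n_permutations=99, seed=1)
    assert res.p_perm == pytest.approx(1 / 100)


def test_permanova_group_validation():
    D = np.zeros((3, 3))
    with pytest.raises(ValueError):
        permanova(D, ["a", "a", "b"])  # group of size 1
    with pytest.raises(ValueError):
        permanova(D, ["a", "a", "a"])  # single group


def test_anosim_perfect_separation_r_one():
    n = 8
    D = np.full((2 * n, 2 * n), 0.9)
    D[:n, :n] = 0.1
    D[n:, n:] = 0.1
    np.fill_diagonal(D, 0.0)
    labels = np.array(["a"] * n + ["b"] * n)
    res = anosim(D, labels, n_permutations=99, seed=0)
    assert res.R == pytest.approx(1.0)
    assert res.p_perm == pytest.approx(1 / 100)


def test_anosim_matches_skbio_and_bounded():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(8)
    for _ in range(3):
        X = rng.gamma(2.0, size=(10, 5))
        D = bray_curtis_matrix(X)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        dm = skbio_distance.DistanceMatrix(D, ids=[str(i) for i in range(10)])
        ref = skbio_distance.anosim(dm, grouping=list(labels), permutations=9)
        res = anosim(D, labels, n_permutations=9, seed=0)
        assert res.R == pytest.approx(ref["test statistic"], rel=1e-10)
        assert -1 <= res.R <= 1


# ---------------------------------------------------------------------------
# Permutation screen


def test_screen_alpha_zero_flags_nothing():
    rng = np.random.default_rng(0)
    X = rng.lognormal(size=(20, 10))
    labels = np.array(["dry"] * 11 + ["wet"] * 9)
    res = permutation_screen(X, labels, n_permutations=50, alpha=0.0, seed=0)
    assert not res.significant.any()


def test_screen_flags_a_strongly_shifted_feature():
    rng = np.random.default_rng(1)
    X = rng.normal(10.0, 1.0, size=(20, 8))
    X[10:, 0] += 10.0  # one feature shifted by ten standard deviations
    labels = np.array(["dry"] * 10 + ["wet"] * 10)
    res = permutation_screen(X, labels, n_permutations=250, alpha=0.05, seed=3)
    assert res.significant[0]
    # the null features are mostly quiet
    assert res.significant[1:].sum() <= 2


def test_screen_reproducible_under_fixed_seed():
    rng = np.random.default_rng(2)
    X = rng.lognormal(size=(20, 12))
    labels = np.array(["dry"] * 11 + ["wet"] * 9)
    a = permutation_screen(X, labels, n_permutations=100, seed=42)
    b = permutation_screen(X, labels, n_permutations=100, seed=42)
    assert a.table.equals(b.table)


def test_screen_significance_respects_threshold_invariant():
    rng = np.random.default_rng(5)
    X = rng.lognormal(size=(16, 20))
    labels = np.array(["dry"] * 8 + ["wet"] * 8)
    res = permutation_screen(X, labels, n_permutations=200, seed=7)
    t = res.table
    flagged = t[t["significant"]]
    assert (flagged["p_real"] <= flagged["p_threshold"] + 1e-12).all()


def test_screen_warns_when_permutations_cannot_resolve_alpha():
    rng = np.random.default_rng(6)
    X = rng.lognormal(size=(10, 3))
    labels = np.array(["dry"] * 5 + ["wet"] * 5)
    with pytest.warns(UserWarning):
        permutation_screen(X, labels, n_permutations=10, alpha=0.05, seed=0)
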