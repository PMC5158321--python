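"""Variance and P-value filters, mRMR-MIQ, PCA/SVD, against oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from psmmkit.selection import (
    PValueProfile,
    VarianceProfile,
    compute_variances,
    mrmr_miq_select,
    pca_reduce,
    pvalue_select,
    svd_reduce,
    ttest_pvalues,
    variance_select,
)
from tests.conftest import make_matrix


class TestVariances:
    def test_identical_rows_have_zero_variance(self):
        fm = make_matrix([[1, 2, 3], [1, 2, 3]], ["A", "B"])
        profile = compute_variances(fm)
        assert profile.total == 0.0

    def test_two_sample_closed_form(self):
        fm = make_matrix([[1], [3]], ["A", "B"])
        assert compute_variances(fm).variances[0] == pytest.approx(2.0)

    def test_matches_definition_level_computation(self, rng):
        x = rng.integers(0, 9, size=(6, 10))
        fm = make_matrix(x, ["A"] * 3 + ["B"] * 3)
        profile = compute_variances(fm)
        for j in range(10):
            col = x[:, j].astype(float)
            expected = ((col - col.mean()) ** 2).sum() / (len(col) - 1)
            assert profile.variances[j] == pytest.approx(expected)
        assert profile.total == pytest.approx(profile.variances.sum())

    def test_single_sample_rejected(self):
        fm = make_matrix([[1, 2]], ["A"])
        with pytest.raises(ValueError):
            compute_variances(fm)

    def test_population_variance_option(self):
        fm = make_matrix([[1], [3]], ["A", "B"])
        assert compute_variances(fm, ddof=0).variances[0] == pytest.approx(1.0)


def prefix_oracle(variances, P):
    """Smallest decreasing-variance prefix whose sum covers P% of the total."""
    order = sorted(range(len(variances)), key=lambda j: (-variances[j], j))
    cutoff = P * sum(variances) / 100.0
    total = 0.0
    for k, j in enumerate(order, start=1):
        total += variances[j]
        if total >= cutoff - 1e-12:
            return order[:k]
    return order


class TestVarianceSelect:
    def test_realized_cutoff_half_of_total(self):
        # total variance 8.5 at P = 50% gives a cumulative cutoff of 4.25
        profile = VarianceProfile(np.array([4.0, 2.0, 1.5, 0.5, 0.5]))
        assert profile.total == pytest.approx(8.5)
        result = variance_select(profile, 50)
        assert result.realized_cutoff == pytest.approx(4.25)
        # prefix sum 6.0 is the first to exceed 4.25: two features kept
        assert [result.criterion[i] for i in range(len(result))] == [4.0, 2.0]

    def test_cumulative_exactly_equal_stops_prefix(self):
        result = variance_select(VarianceProfile(np.array([4.0, 2, 1, 1])), 50)
        assert result.selected == (0,)

    def test_full_threshold_drops_only_zero_variance_features(self):
        result = variance_select(VarianceProfile(np.array([2.0, 0.0, 1.0])), 100)
        assert set(result.selected) == {0, 2}

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError, match="no variation"):
            variance_select(VarianceProfile(np.zeros(3)), 50)

    @pytest.mark.parametrize("P", [0, -5, 101])
    def test_threshold_out_of_range_rejected(self, P):
        with pytest.raises(ValueError):
            variance_select(VarianceProfile(np.ones(3)), P)

    def test_matches_prefix_oracle_on_random_profiles(self, rng):
        for _ in range(100):
            v = rng.exponential(1.0, size=30)
            P = float(rng.uniform(1, 100))
            result = variance_select(VarianceProfile(v), P)
            assert list(result.selected) == prefix_oracle(v.tolist(), P)

    def test_boundary_condition_of_the_cumulative_rule(self, rng):
        v = rng.exponential(1.0, size=25)
        result = variance_select(VarianceProfile(v), 37.0)
        kept = sum(result.criterion)
        assert kept >= result.realized_cutoff - 1e-9
        if len(result) > 1:
            assert kept - result.criterion[-1] < result.realized_cutoff

    def test_nesting_in_threshold(self, rng):
        v = rng.exponential(1.0, size=40)
        profile = VarianceProfile(v)
        small = set(variance_select(profile, 20).selected)
        large = set(variance_select(profile, 70).selected)
        assert small <= large


class TestTtestPvalues:
    def test_constant_equal_feature_gets_p_one(self):
        fm = make_matrix([[3], [3], [3], [3]], ["A", "A", "B", "B"])
        assert ttest_pvalues(fm).pvalues[0] == 1.0

    def test_constant_distinct_means_get_p_zero(self):
        fm = make_matrix([[0], [0], [5], [5]], ["A", "A", "B", "B"])
        assert ttest_pvalues(fm).pvalues[0] == 0.0

    def test_matches_first_principles_welch(self, rng):
        x = rng.integers(0, 9, size=(20, 6)).astype(float)
        fm = make_matrix(x.astype(int), ["A"] * 10 + ["B"] * 10)
        p = ttest_pvalues(fm).pvalues
        a, b = x[:10], x[10:]
        for j in range(6):
            va, vb = a[:, j].var(ddof=1), b[:, j].var(ddof=1)
            se2 = va / 10 + vb / 10
            t = (a[:, j].mean() - b[:, j].mean()) / math.sqrt(se2)
            df = se2**2 / ((va / 10) ** 2 / 9 + (vb / 10) ** 2 / 9)
            expected = 2 * stats.t.sf(abs(t), df)
            assert p[j] == pytest.approx(expected, rel=1e-10)

    def test_pooled_option_matches_student(self, rng):
        x = rng.integers(0, 9, size=(12, 4)).astype(int)
        fm = make_matrix(x, ["A"] * 6 + ["B"] * 6)
        p = ttest_pvalues(fm, equal_var=True).pvalues
        ref = stats.ttest_ind(x[:6], x[6:], equal_var=True).pvalue
        assert p == pytest.approx(ref)

    def test_small_class_rejected(self):
        fm = make_matrix([[1, 2], [3, 4], [5, 6]], ["A", "B", "B"])
        with pytest.raises(ValueError):
            ttest_pvalues(fm)


class TestPvalueSelect:
    def test_half_of_twenty_is_ten(self):
        profile = PValueProfile(np.linspace(0.01, 0.99, 20))
        result = pvalue_select(profile, 50)
        assert len(result) == 10
        assert result.realized_cutoff == 10

    def test_full_threshold_selects_everything(self):
        profile = PValueProfile(np.linspace(0, 1, 7))
        assert len(pvalue_select(profile, 100)) == 7

    def test_floor_with_minimum_one(self):
        profile = PValueProfile(np.array([0.5, 0.2, 0.9]))
        result = pvalue_select(profile, 10)  # floor(0.3) -> min 1
        assert result.selected == (1,)

    def test_selection_ordered_by_increasing_p(self, rng):
        p = rng.uniform(size=50)
        result = pvalue_select(PValueProfile(p), 40)
        assert list(result.criterion) == sorted(result.criterion)
        expected = sorted(range(50), key=lambda j: (p[j], j))[:20]
        assert list(result.selected) == expected

    def test_nesting_in_threshold(self, rng):
        p = rng.uniform(size=30)
        profile = PValueProfile(p)
        assert set(pvalue_select(profile, 20).selected) <= set(
            pvalue_select(profile, 60).selected
        )

    @pytest.mark.parametrize("T", [0, 120])
    def test_threshold_out_of_range_rejected(self, T):
        with pytest.raises(ValueError):
            pvalue_select(PValueProfile(np.array([0.5])), T)


def exhaustive_mrmr_oracle(matrix, k):
    """Independent greedy MIQ: re-derives MI from contingency tables."""
    from collections import Counter

    def discretize(col):
        mu, sd = col.mean(), col.std(ddof=1)
        sd = sd if sd > 0 else 1.0
        z = (col - mu) / sd
        return np.digitize(z, [-0.5, 0.5])

    def mi(u, v):
        n = len(u)
        cu, cv = Counter(u.tolist()), Counter(v.tolist())
        cuv = Counter(zip(u.tolist(), v.tolist()))
        total = 0.0
        for (a, b), c in cuv.items():
            total += (c / n) * math.log(c * n / (cu[a] * cv[b]))
        return max(total, 0.0)

    x = matrix.values.astype(float)
    y = np.array([matrix.classes.index(l) for l in matrix.labels])
    cols = [discretize(x[:, j]) for j in range(x.shape[1])]
    rel = [mi(cols[j], y) for j in range(x.shape[1])]
    chosen = [int(np.argmax(rel))]
    while len(chosen) < k:
        best, best_q = None, -np.inf
        for j in range(x.shape[1]):
            if j in chosen:
                continue
            red = np.mean([mi(cols[j], cols[s]) for s in chosen])
            q = rel[j] / red if red > 0 else np.inf
            if q > best_q:
                best, best_q = j, q
        chosen.append(best)
    return chosen


class TestMrmr:
    def test_k_one_maximizes_label_mi(self, rng):
        noise = rng.integers(0, 5, size=(20, 5))
        separating = np.array([0] * 10 + [9] * 10).reshape(-1, 1)
        x = np.hstack([noise[:, :2], separating, noise[:, 2:]])
        fm = make_matrix(x, ["A"] * 10 + ["B"] * 10)
        result = mrmr_miq_select(fm, 1)
        assert result.selected == (2,)

    def test_perfect_separator_is_picked_first(self, rng):
        x = rng.integers(0, 4, size=(16, 6))
        x[:, 4] = [0] * 8 + [7] * 8
        fm = make_matrix(x, ["A"] * 8 + ["B"] * 8)
        assert mrmr_miq_select(fm, 3).selected[0] == 4

    def test_matches_exhaustive_greedy_oracle(self, rng):
        x = rng.integers(0, 6, size=(14, 6))
        fm = make_matrix(x, ["A"] * 7 + ["B"] * 7)
        result = mrmr_miq_select(fm, 3)
        assert list(result.selected) == exhaustive_mrmr_oracle(fm, 3)

    def test_k_out_of_range_rejected(self):
        fm = make_matrix(np.zeros((4, 3), dtype=int), ["A", "A", "B", "B"])
        with pytest.raises(ValueError):
            mrmr_miq_select(fm, 4)


class TestTransforms:
    def test_rank_one_data_is_explained_by_one_component(self, rng):
        base = rng.integers(1, 5, size=8)
        x = np.outer(rng.integers(0, 6, size=10), base) + 3
        fm = make_matrix(x, ["A"] * 5 + ["B"] * 5)
        scores = pca_reduce(fm, 2)
        # all variance in component 1: component 2 scores are ~0
        assert np.abs(scores[:, 1]).max() < 1e-6 * np.abs(scores[:, 0]).max()

    def test_pca_full_rank_reconstructs_centered_matrix(self, rng):
        x = rng.integers(0, 9, size=(6, 4))
        fm = make_matrix(x, ["A"] * 3 + ["B"] * 3)
        from sklearn.decomposition import PCA

        pca = PCA(n_components=4, svd_solver="full").fit(x.astype(float))
        scores = pca_reduce(fm, 4)
        reconstructed = scores @ pca.components_ + x.mean(axis=0)
        assert np.allclose(reconstructed, x, atol=1e-8)

    def test_pca_variances_match_singular_values(self, rng):
        x = rng.normal(size=(10, 15))
        fm = make_matrix(np.round(x * 100).astype(int), ["A"] * 5 + ["B"] * 5)
        scores = pca_reduce(fm, 5)
        centered = fm.values - fm.values.mean(axis=0)
        s = np.linalg.svd(centered.astype(float), compute_uv=False)
        explained = scores.var(axis=0, ddof=1)
        assert np.allclose(explained, s[:5] ** 2 / 9, rtol=1e-8)

    def test_svd_full_rank_reconstructs_matrix(self, rng):
        x = rng.integers(0, 9, size=(5, 7))
        fm = make_matrix(x, ["A"] * 2 + ["B"] * 3)
        u, s, vt = np.linalg.svd(x.astype(float), full_matrices=False)
        scores = svd_reduce(fm, 5)
        assert np.allclose(scores @ vt, x, atol=1e-8)

    def test_svd_column_norms_are_singular_values(self, rng):
        x = rng.integers(0, 9, size=(6, 9))
        fm = make_matrix(x, ["A"] * 3 + ["B"] * 3)
        scores = svd_reduce(fm, 4)
        s = np.linalg.svd(x.astype(float), compute_uv=False)
        assert np.allclose(np.linalg.norm(scores, axis=0), s[:4])

    @pytest.mark.parametrize("reduce", [pca_reduce, svd_reduce])
    def test_k_out_of_range_rejected(self, reduce):
        fm = make_matrix(np.eye(3, dtype=int), ["A", "A", "B"])
        with pytest.raises(ValueError):
            reduce(fm, 99)


class TestScaleConsistency:
    def test_selection_membership_is_scale_invariant(self, rng):
        x = rng.integers(0, 9, size=(12, 8))
        fm1 = make_matrix(x, ["A"] * 6 + ["B"] * 6)
        fm3 = make_matrix(x * 3, ["A"] * 6 + ["B"] * 6)
        v1 = variance_select(compute_variances(fm1), 60).selected
        v3 = variance_select(compute_variances(fm3), 60).selected
        assert v1 == v3
        p1 = pvalue_select(ttest_pvalues(fm1), 50).selected
        p3 = pvalue_select(ttest_pvalues(fm3), 50).selected
        assert p1 == p3
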