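"""ANOVA F, MCFS relative importance and the product ranking."""

import math

import numpy as np
import pytest
from scipy import stats

from compartmarks.ranking import (
    MCFSParams,
    anova_f,
    mcfs_relative_importance,
    minmax_normalize,
    per_feature_auc,
    product_rank,
)

from conftest import random_matrix


class TestAnovaF:
    def test_equal_class_means_gives_zero(self):
        values = np.array([1, 2, 3, 1, 2, 3], dtype=float)
        labels = np.array(["A"] * 3 + ["B"] * 3)
        assert anova_f(values, labels) == 0.0

    def test_zero_within_variance_gives_infinity(self):
        values = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array(["A", "A", "B", "B"])
        assert anova_f(values, labels) == math.inf

    def test_all_constant_gives_zero(self):
        values = np.zeros(6)
        labels = np.array(["A"] * 3 + ["B"] * 3)
        assert anova_f(values, labels) == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            anova_f(np.arange(4.0), np.array(["A"] * 4))

    def test_equals_squared_t_statistic(self, rng):
        """Two-group one-way ANOVA F is exactly the pooled-variance t**2."""
        for _ in range(300):
            n_a = int(rng.integers(3, 40))
            n_b = int(rng.integers(3, 40))
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n_a)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), n_b)
            values = np.concatenate([a, b])
            labels = np.array(["A"] * n_a + ["B"] * n_b)
            t, _ = stats.ttest_ind(a, b, equal_var=True)
            assert anova_f(values, labels) == pytest.approx(t**2, rel=1e-9)

    def test_matches_scipy_f_oneway(self, rng):
        a = rng.normal(0, 1, 25)
        b = rng.normal(0.7, 1.3, 31)
        f_ref = stats.f_oneway(a, b).statistic
        values = np.concatenate([a, b])
        labels = np.array(["A"] * 25 + ["B"] * 31)
        assert anova_f(values, labels) == pytest.approx(f_ref, rel=1e-12)

    def test_affine_invariance(self, rng):
        values = rng.normal(size=30)
        labels = np.array(["A", "B"] * 15)
        base = anova_f(values, labels)
        assert anova_f(3.5 * values - 11.0, labels) == pytest.approx(base, rel=1e-9)


class TestMinmaxNormalize:
    def test_simple(self):
        assert minmax_normalize(np.array([2.0, 4.0, 6.0])) == pytest.approx(
            [0.0, 0.5, 1.0]
        )

    def test_constant_vector_maps_to_zeros(self):
        assert np.all(minmax_normalize(np.array([3.0, 3.0, 3.0])) == 0.0)

    def test_infinity_sentinel_maps_to_max(self):
        out = minmax_normalize(np.array([1.0, 5.0, math.inf]))
        assert out[2] == 1.0
        assert out[2] > out[1] > out[0]

    def test_range_is_unit_for_nonconstant(self, rng):
        for _ in range(20):
            out = minmax_normalize(rng.normal(size=10))
            assert out.min() == 0.0 and out.max() == 1.0
            assert np.all((out >= 0) & (out <= 1))


class TestProductRank:
    def test_basic_ranks(self):
        table = product_rank(np.array([1.0, 0.0]), np.array([1.0, 0.0]), ["x", "y"])
        assert list(table["feature"]) == ["x", "y"]
        assert list(table["product"]) == [1.0, 0.0]
        assert list(table["rank"]) == [1, 2]

    def test_zero_f_annihilates(self):
        # feature with minimum F gets F_norm 0, hence product 0, whatever its RI
        table = product_rank(
            np.array([9.0, 1.0, 5.0]), np.array([0.0, 2.0, 4.0]), ["a", "b", "c"]
        )
        row = table[table["feature"] == "a"].iloc[0]
        assert row["product"] == 0.0 and row["rank"] > 1

    def test_ranks_are_permutation(self, rng):
        for _ in range(20):
            d = int(rng.integers(2, 30))
            table = product_rank(rng.uniform(size=d), rng.uniform(size=d))
            assert sorted(table["rank"]) == list(range(1, d + 1))

    def test_tie_break_by_raw_ri_then_name(self):
        # both features have product 0 (constant F); larger raw RI first
        table = product_rank(np.array([1.0, 2.0]), np.array([3.0, 3.0]), ["a", "b"])
        assert list(table["feature"]) == ["b", "a"]
        table = product_rank(np.array([1.0, 1.0]), np.array([3.0, 3.0]), ["b", "a"])
        assert list(table["feature"]) == ["a", "b"]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            product_rank(np.zeros(3), np.zeros(2))


class TestMCFS:
    def test_reproducible_given_seed(self, rng):
        matrix = random_matrix(rng, n=80, d=8, informative=1)
        params = MCFSParams(s=40, t=2, seed=7)
        a = mcfs_relative_importance(matrix, params)
        b = mcfs_relative_importance(matrix, MCFSParams(s=40, t=2, seed=7))
        assert np.array_equal(a, b)
        assert a.sum() > 0

    def test_never_drawn_feature_has_zero_ri(self, rng):
        matrix = random_matrix(rng, n=60, d=10, informative=1)
        # m=1: each projection uses a single feature; with few projections
        # some features are never drawn and must score exactly 0
        params = MCFSParams(s=4, m=1, t=1, seed=3)
        ri = mcfs_relative_importance(matrix, params)
        assert np.sum(ri == 0.0) >= 10 - 4

    def test_perfect_feature_attains_max_ri(self, rng):
        wins = 0
        for seed in range(8):
            matrix = random_matrix(rng, n=200, d=12, informative=0)
            # plant a perfectly separating feature in column 0
            matrix.values[:, 0] = (matrix.labels == "A").astype(float)
            ri = mcfs_relative_importance(matrix, MCFSParams(s=60, t=3, seed=seed))
            wins += int(np.argmax(ri) == 0)
        assert wins >= 7

    def test_label_permutation_destroys_importance(self, rng):
        matrix = random_matrix(rng, n=150, d=10, informative=0)
        matrix.values[:, 0] = (matrix.labels == "A").astype(float) + rng.normal(
            0, 0.05, 150
        )
        params = MCFSParams(s=50, t=3, seed=1)
        ri_true = mcfs_relative_importance(matrix, params)
        assert np.argmax(ri_true) == 0
        perm_ranks = []
        for seed in range(5):
            permuted = random_matrix(rng, n=150, d=10)
            permuted.values[:] = matrix.values
            permuted.labels = matrix.labels[
                np.random.default_rng(seed).permutation(150)
            ]
            ri_perm = mcfs_relative_importance(permuted, params)
            perm_ranks.append(np.argsort(-ri_perm).tolist().index(0))
        # after permutation the planted feature is no longer reliably on top
        assert np.mean(perm_ranks) > 1.0

    def test_column_order_invariance_up_to_tree_tie_breaking(self, rng):
        """Permuting columns (and un-permuting the result) preserves the RI
        of the strongly informative features and their top ranks; exact
        per-noise-feature values may shift because tree induction visits
        candidate features in seeded order."""
        matrix = random_matrix(rng, n=100, d=6, informative=2)
        params = MCFSParams(s=30, m=6, t=2, seed=5)  # m=d: every draw = all columns
        base = mcfs_relative_importance(matrix, params)
        perm = np.array([3, 1, 5, 0, 2, 4])
        shuffled = random_matrix(rng, n=100, d=6)
        shuffled.values = matrix.values[:, perm]
        shuffled.descriptors = [matrix.descriptors[i] for i in perm]
        shuffled.labels = matrix.labels
        shuffled.region_ids = matrix.region_ids
        out = mcfs_relative_importance(shuffled, params)
        unperm = np.empty_like(out)
        unperm[perm] = out
        # informative columns 0 and 1 dominate in both runs, with close RI
        assert set(np.argsort(-base)[:2]) == set(np.argsort(-unperm)[:2]) == {0, 1}
        assert np.allclose(unperm[:2], base[:2], rtol=0.15)

    def test_bad_params(self, rng):
        matrix = random_matrix(rng, n=40, d=4)
        with pytest.raises(ValueError):
            mcfs_relative_importance(matrix, MCFSParams(m=10))
        with pytest.raises(ValueError):
            mcfs_relative_importance(matrix, MCFSParams(s=0))


class TestPerFeatureAuc:
    def test_label_identical_feature_is_perfect(self, rng):
        matrix = random_matrix(rng, n=100, d=2)
        matrix.values[:, 0] = (matrix.labels == "A").astype(float)
        mean, sd = per_feature_auc(matrix, "m0:fraction", k=10, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_noise_feature_near_half_and_flips_between(self, rng):
        matrix = random_matrix(rng, n=400, d=2)
        null_mean, _ = per_feature_auc(matrix, "m0:fraction", k=10, seed=0)
        assert 0.38 < null_mean < 0.62
        flipped = (matrix.labels == "A").astype(float)
        flip_idx = rng.choice(400, size=80, replace=False)
        flipped[flip_idx] = 1 - flipped[flip_idx]
        matrix.values[:, 1] = flipped
        noisy_mean, _ = per_feature_auc(matrix, "m1:fraction", k=10, seed=0)
        assert null_mean < noisy_mean < 1.0

    def test_small_class_errors(self, rng):
        matrix = random_matrix(rng, n=12, d=1)
        with pytest.raises(ValueError, match="k=10"):
            per_feature_auc(matrix, "m0:fraction", k=10, seed=0)
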