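from collections import Counter
from itertools import combinations, permutations

import numpy as np
import pandas as pd
import pytest

from phylothreat import (
    Phylogeny,
    build_proximity,
    corrected_rank_correlation,
    mean_shift_test,
    morans_i,
    order_level_correlation,
    phi_matrix,
    threat_counts,
)
from phylothreat.threat_stats import restricted_permutation


def frame(values, species=None, threats=None):
    values = np.asarray(values)
    species = species or [f"s{i}" for i in range(values.shape[0])]
    threats = threats or [f"t{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=species, columns=threats)


class TestPhi:
    def test_identical_and_complementary_columns(self):
        inc = frame([[1, 0], [1, 0], [0, 1], [0, 1]])
        phi = phi_matrix(inc)
        assert phi.iloc[0, 1] == pytest.approx(-1.0)
        inc2 = frame([[1, 1], [0, 0], [1, 1], [0, 0]])
        assert phi_matrix(inc2).iloc[0, 1] == pytest.approx(1.0)

    def test_matches_product_moment_correlation(self, rng):
        inc = frame(rng.integers(0, 2, (40, 5)))
        phi = phi_matrix(inc)
        for i in range(5):
            for j in range(i + 1, 5):
                a, b = inc.values[:, i], inc.values[:, j]
                if a.std() == 0 or b.std() == 0:
                    continue
                assert phi.iloc[i, j] == pytest.approx(np.corrcoef(a, b)[0, 1])

    def test_constant_column_yields_missing(self):
        inc = frame([[1, 1], [1, 0], [1, 1]])
        phi = phi_matrix(inc)
        assert np.isnan(phi.iloc[0, 1])

    def test_symmetry_and_relabel_invariance(self, rng):
        inc = frame(rng.integers(0, 2, (25, 4)))
        phi = phi_matrix(inc)
        pd.testing.assert_frame_equal(phi, phi.T, check_names=False)
        flipped = frame(1 - inc.values)
        phi2 = phi_matrix(flipped)
        valid = ~np.isnan(phi.values) & ~np.isnan(phi2.values)
        assert np.allclose(phi.values[valid], phi2.values[valid])


class TestThreatCounts:
    def test_row_sums(self):
        inc = frame([[0] * 11, [1] * 11])
        counts = threat_counts(inc)
        assert counts.tolist() == [0, 11]

    def test_matches_per_row_oracle(self, rng):
        inc = frame(rng.integers(0, 2, (20, 11)))
        assert threat_counts(inc).tolist() == [int(sum(r)) for r in inc.values]


def uniform_w(n):
    W = np.ones((n, n)) - np.eye(n)
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame(W, index=idx, columns=idx)


class TestMoransI:
    def test_uniform_weights_closed_form(self, rng):
        n = 12
        x = pd.Series(rng.poisson(3, n).astype(float), index=[f"s{i}" for i in range(n)])
        x.iloc[0] += 1  # ensure non-constant
        res = morans_i(x, uniform_w(n), n_perm=9, seed=0)
        assert res.statistic == pytest.approx(-1 / (n - 1), abs=1e-12)

    def test_two_block_structure_matches_direct_formula(self):
        n = 8
        idx = [f"s{i}" for i in range(n)]
        W = np.zeros((n, n))
        W[:4, :4] = 1
        W[4:, 4:] = 1
        np.fill_diagonal(W, 0)
        Wdf = pd.DataFrame(W, index=idx, columns=idx)
        x = pd.Series([1.0] * 4 + [5.0] * 4, index=idx)
        res = morans_i(x, Wdf, n_perm=9, seed=0)
        z = x.values - x.values.mean()
        manual = n / W.sum() * (z @ W @ z) / (z @ z)
        assert res.statistic == pytest.approx(manual)
        assert res.statistic == pytest.approx(1.0)  # perfect within-block alignment

    def test_null_expectation_minus_one_over_n_minus_one(self, rng):
        n = 15
        idx = [f"s{i}" for i in range(n)]
        W = rng.uniform(0, 1, (n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        x = pd.Series(rng.normal(size=n), index=idx)
        res = morans_i(x, pd.DataFrame(W, index=idx, columns=idx), n_perm=3000, seed=1)
        se = res.null.std() / np.sqrt(res.null.size)
        assert res.null.mean() == pytest.approx(-1 / (n - 1), abs=4 * se)

    def test_constant_values_rejected(self):
        x = pd.Series([2.0] * 5, index=[f"s{i}" for i in range(5)])
        with pytest.raises(ValueError, match="constant"):
            morans_i(x, uniform_w(5))

    def test_same_seed_identical_null(self, rng):
        n = 10
        x = pd.Series(rng.poisson(2, n).astype(float) + np.arange(n) * 0.01,
                      index=[f"s{i}" for i in range(n)])
        a = morans_i(x, uniform_w(n), n_perm=99, seed=7)
        b = morans_i(x, uniform_w(n), n_perm=99, seed=7)
        assert np.array_equal(a.null, b.null) and a.p_value == b.p_value


class TestRestrictedPermutation:
    def test_uniform_proximities_reduce_to_free_permutation(self):
        """TV distance between the restricted-null arrangement distribution and
        the uniform distribution over all 4! arrangements stays small."""
        rng = np.random.default_rng(3)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        W = np.ones((4, 4)) - np.eye(4)
        counts = Counter()
        n_samples = 3000
        for _ in range(n_samples):
            counts[tuple(restricted_permutation(x, W, rng))] += 1
        arrangements = list(permutations(x))
        tv = 0.5 * sum(
            abs(counts.get(a, 0) / n_samples - 1 / 24) for a in arrangements
        )
        assert tv < 0.05

    def test_permutation_is_a_rearrangement(self, rng):
        x = rng.poisson(2, 20).astype(float)
        W = rng.uniform(0, 1, (20, 20))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        out = restricted_permutation(x, W, rng)
        assert sorted(out) == sorted(x)


class TestCorrectedRankCorrelation:
    def test_monotone_relation_gives_r_one(self):
        idx = [f"s{i}" for i in range(8)]
        x = pd.Series(np.arange(8, dtype=float), index=idx)
        y = pd.Series(np.arange(8, dtype=float) ** 2, index=idx)
        res = corrected_rank_correlation(x, y, uniform_w(8), n_perm=49, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_all_zero_w_falls_back_to_free_permutation(self, rng):
        idx = [f"s{i}" for i in range(10)]
        x = pd.Series(rng.normal(size=10), index=idx)
        y = pd.Series(rng.normal(size=10), index=idx)
        W = pd.DataFrame(np.zeros((10, 10)), index=idx, columns=idx)
        with pytest.warns(UserWarning, match="free permutation"):
            res = corrected_rank_correlation(x, y, W, n_perm=19, seed=0)
        assert 0 < res.p_value <= 1

    def test_constant_input_rejected(self):
        idx = list("abcd")
        x = pd.Series([1.0] * 4, index=idx)
        y = pd.Series([1.0, 2, 3, 4], index=idx)
        with pytest.raises(ValueError, match="constant"):
            corrected_rank_correlation(x, y, None)

    def test_deterministic_under_seed(self, rng):
        idx = [f"s{i}" for i in range(12)]
        x = pd.Series(rng.poisson(2, 12).astype(float) + 0.1 * np.arange(12), index=idx)
        y = pd.Series(rng.normal(size=12), index=idx)
        W = build_proximity("geographic", pd.DataFrame(
            rng.integers(0, 2, (12, 4)), index=idx))
        a = corrected_rank_correlation(x, y, W, n_perm=49, seed=5)
        b = corrected_rank_correlation(x, y, W, n_perm=49, seed=5)
        assert a.p_value == b.p_value and np.array_equal(a.null, b.null)


class TestMeanShift:
    def two_groups(self, lo_vals, hi_vals):
        idx = [f"s{i}" for i in range(len(lo_vals) + len(hi_vals))]
        x = pd.Series(list(lo_vals) + list(hi_vals), index=idx, dtype=float)
        g = pd.Series(["LC"] * len(lo_vals) + ["NT"] * len(hi_vals), index=idx)
        return x, g

    def test_identical_distributions_give_t_zero_p_one(self):
        x, g = self.two_groups([2, 2, 2], [2, 2, 2])
        res = mean_shift_test(x, g, low="LC", high="NT")
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_complete_separation_gives_minimum_p(self):
        x, g = self.two_groups([1, 1, 1, 2], [5, 6, 7])
        res = mean_shift_test(x, g, low="LC", high="NT")
        from math import comb

        assert res.p_value == pytest.approx(1 / comb(7, 3))

    def test_exhaustive_enumeration_is_used_on_small_instances(self):
        x, g = self.two_groups([1, 3, 2, 2], [4, 5, 3])
        res = mean_shift_test(x, g, low="LC", high="NT")
        from math import comb

        assert res.n_perm == comb(7, 3)

    def test_monte_carlo_matches_exhaustive(self, rng):
        """MC permutation p on n=7 agrees with exhaustive enumeration within
        binomial sampling error."""
        x, g = self.two_groups([1, 3, 2, 2], [4, 5, 3])
        exact = mean_shift_test(x, g, low="LC", high="NT")
        mc = mean_shift_test(x, g, low="LC", high="NT", exact_limit=0,
                             n_perm=4000, seed=1)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 4000)
        assert mc.p_value == pytest.approx(exact.p_value, abs=4 * se + 2 / 4000)

    def test_empty_group_rejected(self):
        x, g = self.two_groups([1, 2], [])
        with pytest.raises(ValueError, match="empty group"):
            mean_shift_test(x, g, low="LC", high="NT")


class TestOrderLevelCorrelation:
    def test_identical_vectors_give_r_one(self):
        a = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        out = order_level_correlation(a, a)
        assert out["raw"]["r"] == pytest.approx(1.0)
        assert out["rank"]["r"] == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        idx = [f"o{i}" for i in range(23)]
        a = pd.Series(rng.normal(size=23), index=idx)
        b = pd.Series(rng.normal(size=23), index=idx)
        out = order_level_correlation(a, b)
        av, bv = a.values, b.values
        manual = ((av - av.mean()) @ (bv - bv.mean())) / (
            np.sqrt(((av - av.mean()) ** 2).sum() * ((bv - bv.mean()) ** 2).sum())
        )
        assert out["raw"]["r"] == pytest.approx(manual)
        assert out["raw"]["df"] == 21
        expected_t = manual * np.sqrt(21 / (1 - manual**2))
        assert out["raw"]["t"] == pytest.approx(expected_t)

    def test_two_clades_rejected(self):
        a = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(ValueError, match="at least 3"):
            order_level_correlation(a, a)


class TestBuildProximity:
    def test_phylogenetic_bounds(self, three_tip_tree):
        W = build_proximity("phylogenetic", three_tip_tree)
        assert W.loc["A", "C"] == pytest.approx(0.0)  # maximal distance pair
        assert W.loc["A", "B"] == pytest.approx(0.5)  # (4-2)/4
        assert np.allclose(np.diag(W.values), 0.0)

    def test_identical_label_sets_give_one(self):
        inc = pd.DataFrame([[1, 1, 0], [1, 1, 0], [0, 0, 1]],
                           index=list("abc"), columns=["x", "y", "z"])
        W = build_proximity("geographic", inc)
        assert W.loc["a", "b"] == pytest.approx(1.0)
        assert W.loc["a", "c"] == pytest.approx(0.0)

    def test_random_inputs_valid_proximity(self, rng):
        inc = pd.DataFrame(rng.integers(0, 2, (15, 5)),
                           index=[f"s{i}" for i in range(15)])
        W = build_proximity("habitat", inc)
        V = W.values
        assert np.allclose(V, V.T)
        assert np.allclose(np.diag(V), 0)
        assert V.min() >= 0 and V.max() <= 1

    def test_empty_label_set_warns(self):
        inc = pd.DataFrame([[0, 0], [1, 0]], index=list("ab"))
        with pytest.warns(UserWarning, match="empty label"):
            W = build_proximity("geographic", inc)
        assert W.loc["a", "b"] == 0
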