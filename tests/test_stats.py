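import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rateherit.stats import (
    coefficient_of_variation,
    histogram,
    histogram_mode_bin,
    mann_whitney_u,
    pca,
    spearman_rho,
    two_proportion_z,
)


def exact_mwu_p(x, y):
    """Enumerate all labelings of the pooled sample (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    n = len(pooled)
    mean_u = n1 * (len(y)) / 2
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        vals = [pooled[i] for i in combo]
        u = sum(ranks[v] for v in vals) - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.method == "mwu-exact"
        assert res.p_value == pytest.approx(exact_mwu_p([1, 2, 3], [4, 5, 6]))

    def test_exact_matches_enumeration_oracle(self):
        x, y = [0.3, 1.7, 2.2, 5.0], [0.9, 2.5, 3.1]
        res = mann_whitney_u(x, y)
        assert res.method == "mwu-exact"
        assert res.p_value == pytest.approx(exact_mwu_p(x, y), abs=1e-12)

    def test_u_statistics_sum_to_n1n2(self, rng):
        x = rng.normal(size=25)
        y = rng.normal(size=18)
        ux = mann_whitney_u(x, y).statistic
        uy = mann_whitney_u(y, x).statistic
        assert ux + uy == pytest.approx(25 * 18)

    def test_identical_multisets_give_central_u(self):
        x = [1.0, 2.0, 3.0, 4.0] * 5
        res = mann_whitney_u(x, list(x))
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.p_value >= 0.99

    def test_zero_variance_flagged(self):
        res = mann_whitney_u([5, 5, 5], [5, 5])
        assert res.p_value == 1.0
        assert "zero_variance" in res.flags

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney_u([1, 1, 2], [2, 3, 3])
        assert res.method == "mwu-asymptotic"

    def test_null_rejection_rate_calibrated(self, rng):
        """Type-I error near nominal alpha for two same-distribution samples."""
        rejections = 0
        reps = 1000
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            if mann_whitney_u(x, y).p_value < 0.05:
                rejections += 1
        assert 0.03 < rejections / reps < 0.07


class TestSpearman:
    def test_monotone_relations(self):
        x = [1, 2, 3, 4, 5]
        assert spearman_rho(x, [2, 4, 9, 16, 30]).statistic == pytest.approx(1.0)
        assert spearman_rho(x, [-1, -2, -3, -4, -5]).statistic == pytest.approx(-1.0)

    def test_tied_example_matches_pearson_on_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
        y = [4.0, 4.0, 6.0, 2.0, 9.0, 8.0]
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_rho(x, y).statistic == pytest.approx(expected, abs=1e-12)

    def test_missing_pairs_dropped(self):
        x = [1, 2, np.nan, 4, 5, 6]
        y = [2, 3, 1, np.nan, 9, 11]
        res = spearman_rho(x, y)
        assert res.n1 == 4
        assert res.statistic == pytest.approx(1.0)

    def test_antisymmetric_under_order_reversal(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        r1 = spearman_rho(x, y).statistic
        r2 = spearman_rho(-x, y).statistic
        assert r1 == pytest.approx(-r2, abs=1e-12)
        assert -1 <= r1 <= 1

    def test_zero_rank_variance_flagged(self):
        res = spearman_rho([1, 1, 1], [1, 2, 3])
        assert "zero_rank_variance" in res.flags


class TestCoefficientOfVariation:
    def test_constant_vector_zero(self):
        assert coefficient_of_variation([3, 3, 3]) == 0.0

    def test_hand_arithmetic(self):
        assert coefficient_of_variation([1, 3]) == pytest.approx(np.sqrt(2) / 2)

    def test_scale_invariance(self, rng):
        x = rng.gamma(2.0, 3.0, size=50)
        assert coefficient_of_variation(x) == pytest.approx(
            coefficient_of_variation(7.3 * x)
        )

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([-1, 1])


class TestTwoProportionZ:
    def test_equal_proportions_zero(self):
        res = two_proportion_z(5, 10, 50, 100)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_pooled_formula(self):
        k1, n1, k2, n2 = 10, 100, 90, 100
        p1, p2 = k1 / n1, k2 / n2
        pp = (k1 + k2) / (n1 + n2)
        z_expected = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        res = two_proportion_z(k1, n1, k2, n2)
        assert res.statistic == pytest.approx(z_expected, abs=1e-12)
        assert res.p_value == pytest.approx(
            2 * sps.norm.sf(abs(z_expected)), abs=1e-12
        )

    def test_sign_convention(self):
        assert two_proportion_z(10, 100, 50, 100).statistic < 0

    def test_degenerate_pooled_proportion(self):
        with pytest.raises(ValueError):
            two_proportion_z(0, 10, 0, 10)


class TestPca:
    def test_perfectly_correlated_pair(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = pca(df)
        assert res.component_variance_pct[0] == pytest.approx(100.0)

    def test_variance_sums_to_100(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 6)), columns=list("abcdef"))
        res = pca(df)
        assert res.component_variance_pct.sum() == pytest.approx(100.0, abs=1e-6)

    def test_independent_variables_near_uniform_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(5000, 4)), columns=list("abcd"))
        res = pca(df)
        assert np.allclose(res.component_variance_pct, 25.0, atol=3.0)

    def test_loadings_reconstruct_correlation_matrix(self, rng):
        base = rng.normal(size=(300, 2))
        df = pd.DataFrame(
            np.column_stack([base[:, 0], base[:, 0] + rng.normal(size=300),
                             base[:, 1], base[:, 1] * 2 + rng.normal(size=300)]),
            columns=list("wxyz"),
        )
        res = pca(df)
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        recon = res.loadings.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(recon, corr, atol=1e-8)
        assert (np.abs(res.loadings.to_numpy()) <= 1 + 1e-9).all()

    def test_invariant_to_row_order(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 3)), columns=list("abc"))
        res1 = pca(df)
        res2 = pca(df.sample(frac=1.0, random_state=0))
        assert np.allclose(
            res1.component_variance_pct, res2.component_variance_pct
        )
        assert np.allclose(res1.loadings.to_numpy(), res2.loadings.to_numpy())

    def test_matches_sklearn_on_standardized_data(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        df = pd.DataFrame(rng.normal(size=(150, 5)), columns=list("abcde"))
        res = pca(df)
        z = (df - df.mean()) / df.std(ddof=1)
        ref = sklearn_pca(n_components=5).fit(z.to_numpy())
        ref_pct = 100 * ref.explained_variance_ratio_
        assert np.allclose(res.component_variance_pct, ref_pct, atol=1e-8)

    def test_two_block_structure_recovered(self, rng):
        """Within-block r = 0.7 blocks land in separate components.

        Block sizes differ (4 vs 3) so the two block eigenvalues are
        distinct and the component order is well defined.
        """
        n = 2000
        fa = rng.normal(size=n)
        fb = rng.normal(size=n)
        noise = np.sqrt(1 - 0.7) / np.sqrt(0.7)
        block_a = {f"expr_{i}": fa + noise * rng.normal(size=n) for i in range(4)}
        block_b = {f"len_{i}": fb + noise * rng.normal(size=n) for i in range(3)}
        res = pca(pd.DataFrame({**block_a, **block_b}))
        first_two = {0: set(res.retained[0]), 1: set(res.retained[1])}
        blocks = [set(block_a), set(block_b)]
        assert {frozenset(first_two[0]), frozenset(first_two[1])} == {
            frozenset(blocks[0]),
            frozenset(blocks[1]),
        }

    def test_constant_variable_named_in_error(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=10), "b": np.ones(10)})
        with pytest.raises(ValueError, match="b"):
            pca(df)

    def test_fewer_cases_than_variables_warns(self, rng):
        df = pd.DataFrame(rng.normal(size=(3, 5)), columns=list("abcde"))
        with pytest.warns(UserWarning):
            pca(df)


class TestHistogram:
    def test_single_bin(self):
        h = histogram([0.11, 0.12, 0.19], 0.1)
        assert len(h) == 1
        assert h["frequency_pct"].iloc[0] == pytest.approx(100.0)

    def test_empty_input(self):
        assert histogram([], 0.5).empty

    def test_uniform_values_across_bins(self):
        h = histogram([0.05, 0.15, 0.25, 0.35], 0.1)
        assert np.allclose(h["frequency_pct"], 25.0)
        assert np.allclose(h["bin_center"], [0.05, 0.15, 0.25, 0.35])

    def test_left_closed_bins(self):
        h = histogram([0.1], 0.1)  # 0.1 belongs to [0.1, 0.2)
        assert h["bin_center"].iloc[0] == pytest.approx(0.15)

    def test_mode_bin(self):
        h = histogram([0.01, 0.011, 0.012, 0.05], 0.01)
        center, pct = histogram_mode_bin(h)
        assert center == pytest.approx(0.015)
        assert pct == pytest.approx(75.0)
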