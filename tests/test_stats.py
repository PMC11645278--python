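"""Metrics and inferential statistics: MDE, rmse, chi-square, ANOVA, permutation."""

import numpy as np
import pytest

from brainclock import stats
from brainclock.errors import ContractError, DegenerateInputError


class TestMdeRmse:
    @pytest.mark.parametrize(
        "chron, pred, expect_mde",
        [([70, 80], [75, 85], 5.0), ([60, 70], [58, 69], -1.5), ([50], [50], 0.0)],
    )
    def test_mde_examples(self, chron, pred, expect_mde):
        assert stats.mde(chron, pred) == pytest.approx(expect_mde)

    def test_rmse_example(self):
        assert stats.rmse([0, 0], [3, 4]) == pytest.approx(np.sqrt(12.5))
        assert stats.rmse([1, 2], [1, 2]) == 0.0

    def test_formula_identities_on_random_vectors(self):
        """MDE and rmse agree with direct formula evaluation to 1e-12, and
        rmse >= |mde| (Jensen) on 1,000 random vectors."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 30)
            y = rng.normal(60, 15, n)
            yhat = y + rng.normal(0, 8, n)
            m, r = stats.mde(y, yhat), stats.rmse(y, yhat)
            assert abs(m - np.sum(yhat - y) / n) < 1e-12
            assert abs(r - np.sqrt(np.sum((yhat - y) ** 2) / n)) < 1e-12
            assert r >= abs(m)

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            stats.mde([], [])


class TestCohensF2:
    @pytest.mark.parametrize(
        "r2, expect", [(0.40, 0.67), (0.37, 0.59), (0.0, 0.0)]
    )
    def test_reported_identities(self, r2, expect):
        assert round(stats.cohens_f2(r2), 2) == expect

    def test_r2_of_one_rejected(self):
        with pytest.raises(ContractError):
            stats.cohens_f2(1.0)


class TestOlsMetrics:
    def test_perfect_prediction(self):
        y = np.arange(10.0)
        rep = stats.fit_ols_metrics(y, y)
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)
        assert rep.rmse == 0.0

    def test_null_simulation(self):
        rng = np.random.default_rng(1)
        rep = stats.fit_ols_metrics(rng.normal(60, 10, 1000), rng.normal(60, 10, 1000))
        assert rep.r_squared < 0.01

    def test_hand_computed_r2(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = np.array([1.5, 2.0, 2.5, 4.5, 4.0])
        r2_hand = (np.cov(y, yhat)[0, 1] / (y.std(ddof=1) * yhat.std(ddof=1))) ** 2
        rep = stats.fit_ols_metrics(y, yhat)
        assert rep.r_squared == pytest.approx(r2_hand, abs=1e-10)
        assert rep.cohens_f2 == pytest.approx(r2_hand / (1 - r2_hand), abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            stats.fit_ols_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPermutationTest:
    def test_identical_groups_null(self):
        x = np.arange(20.0)
        res = stats.permutation_subsample_test(x, x, iterations=500, seed=0)
        assert res.p_value > 0.9

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 100)
        b = rng.normal(2, 1, 100)
        res = stats.permutation_subsample_test(a, b, iterations=5000, seed=0)
        assert res.p_value <= 0.001
        assert res.observed_stat == pytest.approx(a.mean() - b.mean())

    def test_unequal_sizes_subsampled(self):
        rng = np.random.default_rng(3)
        res = stats.permutation_subsample_test(
            rng.normal(0, 1, 200), rng.normal(0, 1, 30), iterations=200, seed=1
        )
        assert 0.0 < res.p_value <= 1.0

    def test_p_value_never_zero(self):
        res = stats.permutation_subsample_test([0.0, 0.1], [10.0, 10.1],
                                               iterations=50, seed=0)
        assert res.p_value >= 1.0 / 51.0


class TestChiSquare:
    def test_printed_sex_statistics(self):
        """Contingency statistics for the four demographic sex tables."""
        chi2, df, p = stats.chi_square_test([[470, 99], [954, 532]])
        assert chi2 == pytest.approx(64.62, abs=0.02)
        assert df == 1
        chi2, df, p = stats.chi_square_test(
            [[470, 497], [114, 101], [112, 102], [98, 92]]
        )
        assert chi2 == pytest.approx(2.19, abs=0.02)
        assert p == pytest.approx(0.533, abs=0.002)
        chi2, _, _ = stats.chi_square_test(
            [[261, 216], [84, 85], [262, 243], [105, 111]]
        )
        assert chi2 == pytest.approx(2.76, abs=0.02)
        chi2, _, _ = stats.chi_square_test(
            [[954, 532], [111, 22], [85, 23], [39, 18]]
        )
        assert chi2 == pytest.approx(28.05, abs=0.02)

    def test_yates_flag(self):
        chi2_raw, _, _ = stats.chi_square_test(
            [[470, 99], [954, 532]], yates_for_2x2=False
        )
        assert chi2_raw == pytest.approx(65.48, abs=0.02)

    def test_proportional_rows_zero(self):
        chi2, _, p = stats.chi_square_test([[10, 20], [30, 60]], yates_for_2x2=False)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ContractError):
            stats.chi_square_test([[0, 0], [1, 2]])


class TestAnova:
    def test_hand_oracle(self):
        # groups {1,2,3}, {4,5,6}: SSb = 13.5, SSw = 4, F = 13.5, eta = 27/35
        F, p, eta = stats.one_way_anova_eta([[1, 2, 3], [4, 5, 6]])
        assert F == pytest.approx(13.5)
        assert eta == pytest.approx(13.5 / 17.5)

    def test_identical_groups(self):
        F, p, eta = stats.one_way_anova_eta([[1, 2, 3], [1, 2, 3]])
        assert F == pytest.approx(0.0) and eta == pytest.approx(0.0)

    def test_eta_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            groups = [rng.normal(rng.uniform(-2, 2), 1, 10) for _ in range(3)]
            _, _, eta = stats.one_way_anova_eta(groups)
            assert 0.0 <= eta <= 1.0

    def test_singleton_group_rejected(self):
        with pytest.raises(ContractError):
            stats.one_way_anova_eta([[1.0], [2.0, 3.0]])


class TestCovariateAdjustment:
    def test_uncorrelated_covariate_leaves_gaps(self):
        rng = np.random.default_rng(5)
        gaps = rng.normal(2, 3, 500)
        cov = rng.normal(0, 1, 500)
        adj = stats.covariate_adjust_gaps(gaps, cov)
        assert np.corrcoef(gaps, adj)[0, 1] > 0.99

    def test_linear_gap_becomes_constant(self):
        cov = np.linspace(0, 10, 50)
        gaps = 3.0 * cov + 1.0
        adj = stats.covariate_adjust_gaps(gaps, cov)
        np.testing.assert_allclose(adj, adj[0] * np.ones_like(adj), atol=1e-8)

    def test_balanced_groups_keep_mean_difference(self):
        rng = np.random.default_rng(6)
        n = 400
        cov = np.concatenate([rng.normal(0, 1, n), rng.normal(0, 1, n)])
        gaps = np.concatenate([rng.normal(0, 1, n), rng.normal(2, 1, n)])
        gaps = gaps + 0.5 * cov
        adj = stats.covariate_adjust_gaps(gaps, cov)
        raw_diff = gaps[n:].mean() - gaps[:n].mean()
        adj_diff = adj[n:].mean() - adj[:n].mean()
        assert adj_diff == pytest.approx(raw_diff, abs=0.2)

    def test_collinear_covariates_rejected(self):
        cov = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(DegenerateInputError):
            stats.covariate_adjust_gaps(np.arange(10.0), cov)
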