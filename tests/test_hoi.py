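"""Gaussian-copula entropy and O-information estimation."""

import numpy as np
import pytest
from scipy import stats as sps

from brainclock import hoi
from brainclock.errors import ContractError, DegenerateInputError
from brainclock.synthetic import RegionTimeSeries

LN_2PIE = np.log(2 * np.pi * np.e)


def brute_force_omega_pair(cov, i, j):
    """Independent oracle: three-block O-information of ({i},{j},rest) from
    raw sub-determinants of a covariance matrix (no shared code path)."""
    R = cov.shape[0]
    rest = [r for r in range(R) if r not in (i, j)]

    def H(ix):
        sub = cov[np.ix_(ix, ix)] + 1e-8 * np.eye(len(ix))
        return 0.5 * np.log(((2 * np.pi * np.e) ** len(ix)) * np.linalg.det(sub))

    return (
        H(list(range(R)))
        - H([i, j])
        - H([i] + rest)
        - H([j] + rest)
        + H([i])
        + H([j])
        + H(rest)
    )


class TestCopulaTransform:
    def test_rank_to_normal_quantiles(self):
        out = hoi.copula_transform(np.array([[3.0, 1.0, 2.0]]).T).ravel()
        expect = sps.norm.ppf([0.75, 0.25, 0.5])
        np.testing.assert_allclose(out, expect, atol=1e-12)
        assert out[2] == 0.0  # median maps to zero for odd T

    def test_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 3))
        warped = np.stack([np.exp(x[:, 0]), x[:, 1] ** 3, np.arctan(x[:, 2])], axis=1)
        np.testing.assert_array_equal(
            hoi.copula_transform(x), hoi.copula_transform(warped)
        )

    def test_constant_column_raises(self):
        bad = np.ones((10, 2))
        bad[:, 0] = np.arange(10)
        with pytest.raises(DegenerateInputError, match="column 1"):
            hoi.copula_transform(bad)


class TestEntropy:
    def test_independent_standard_normals(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20000, 2))
        assert hoi.gaussian_copula_entropy(X) == pytest.approx(LN_2PIE, abs=0.01)

    def test_correlated_gaussian_closed_form(self):
        rng = np.random.default_rng(3)
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        X = rng.multivariate_normal([0, 0], cov, size=50000)
        expect = LN_2PIE + 0.5 * np.log(0.75)
        assert hoi.gaussian_copula_entropy(X) == pytest.approx(expect, abs=0.01)

    def test_additivity_under_independence(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((20000, 2))
        X3 = np.hstack([X, rng.standard_normal((20000, 1))])
        gain = hoi.gaussian_copula_entropy(X3) - hoi.gaussian_copula_entropy(X)
        assert gain == pytest.approx(0.5 * LN_2PIE, abs=0.02)


class TestOInformation:
    T = 20000

    def test_independence_null(self):
        X = np.random.default_rng(5).standard_normal((self.T, 3))
        assert abs(hoi.o_information(X)) < 0.02

    def test_common_source_redundancy_positive(self):
        rng = np.random.default_rng(6)
        g = rng.standard_normal(self.T)
        X = np.stack([g + 0.5 * rng.standard_normal(self.T) for _ in range(3)], axis=1)
        assert hoi.o_information(X) > 0.1

    def test_noisy_sum_synergy_negative(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, self.T))
        z = x + y + 0.1 * rng.standard_normal(self.T)
        assert hoi.o_information(np.stack([x, y, z], axis=1)) < -0.1

    def test_needs_three_blocks(self):
        X = np.random.default_rng(8).standard_normal((100, 4))
        with pytest.raises(ContractError):
            hoi.o_information(X, blocks=[[0], [1, 2, 3]])

    def test_general_form_matches_three_block_form(self):
        X = np.random.default_rng(9).standard_normal((500, 3))
        # with singleton blocks both code paths evaluate the same quantity
        om3 = hoi.o_information(X, blocks=[[0], [1], [2]])
        Z = hoi.copula_transform(X)
        cov = np.cov(Z, rowvar=False, ddof=1)
        om_n = hoi.o_information_from_cov(cov, [[0], [1], [2], []][:3])
        assert om3 == pytest.approx(om_n, abs=1e-12)


class TestOmegaMatrix:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        A = rng.standard_normal((5, 5))
        cov = A @ A.T + 5 * np.eye(5)
        m = hoi.omega_matrix_from_cov(cov)
        for i in range(5):
            for j in range(i + 1, 5):
                assert m.values[i, j] == pytest.approx(
                    brute_force_omega_pair(cov, i, j), abs=1e-10
                )

    def test_independent_regions_near_zero(self):
        X = np.random.default_rng(11).standard_normal((20000, 4))
        m = hoi.omega_matrix(RegionTimeSeries("x", X, 2.0))
        off = m.values[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_symmetry_and_zero_diagonal(self):
        X = np.random.default_rng(12).standard_normal((300, 6))
        m = hoi.omega_matrix(RegionTimeSeries("x", X, 2.0))
        np.testing.assert_array_equal(m.values, m.values.T)
        np.testing.assert_array_equal(np.diag(m.values), 0.0)

    def test_region_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((400, 5)) @ rng.standard_normal((5, 5))
        perm = np.array([2, 0, 4, 1, 3])
        m = hoi.omega_matrix(RegionTimeSeries("x", X, 2.0)).values
        mp = hoi.omega_matrix(RegionTimeSeries("x", X[:, perm], 2.0)).values
        np.testing.assert_allclose(mp, m[np.ix_(perm, perm)], atol=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((300, 4)) @ rng.standard_normal((4, 4))
        warped = X.copy()
        warped[:, 0] = np.exp(warped[:, 0])
        warped[:, 2] = warped[:, 2] ** 3
        m1 = hoi.omega_matrix(RegionTimeSeries("x", X, 2.0)).values
        m2 = hoi.omega_matrix(RegionTimeSeries("x", warped, 2.0)).values
        np.testing.assert_allclose(m1, m2, atol=1e-12)


class TestNormalize:
    def test_scaling_contract(self):
        v = np.zeros((3, 3))
        v[0, 1] = v[1, 0] = -0.5
        v[1, 2] = v[2, 1] = 0.25
        m = hoi.normalize_omega(hoi.OmegaMatrix("s", v))
        assert m.values[0, 1] == -1.0
        assert m.values[1, 2] == 0.5
        assert m.normalized

    def test_all_zero_unchanged(self):
        m = hoi.normalize_omega(hoi.OmegaMatrix("s", np.zeros((4, 4))))
        assert m.normalized and not m.values.any()

    def test_idempotent(self):
        rng = np.random.default_rng(15)
        v = rng.standard_normal((4, 4))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        once = hoi.normalize_omega(hoi.OmegaMatrix("s", v))
        twice = hoi.normalize_omega(once)
        np.testing.assert_array_equal(once.values, twice.values)
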