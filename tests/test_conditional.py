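"""Conditional model for correlated effect blocks."""

import numpy as np
import pytest

from gblue.conditional import (
    ConditionalGLS,
    conditional_blup_delta,
    conditional_design,
    conditional_gls,
    fit_conditional,
    signal_decomposition,
)
from gblue.covariance import build_covariances
from gblue.datatypes import EffectCovariance, GenotypeMatrix, VarianceComponents
from gblue.gls import gls_estimate
from gblue.simulate import simulate_effects


def _random_pd_joint(rng, p1, p2):
    a = rng.standard_normal((p1 + p2, p1 + p2 + 3))
    joint = a @ a.T / (p1 + p2 + 3) + 0.2 * np.eye(p1 + p2)
    return EffectCovariance(
        B11=joint[:p1, :p1], B22=joint[p1:, p1:], B12=joint[:p1, p1:]
    )


class TestConditionalDesign:
    def test_independent_blocks_change_nothing(self, rng):
        x1 = rng.standard_normal((6, 2))
        x2 = rng.standard_normal((6, 4))
        b = EffectCovariance(B11=np.eye(2), B22=3.0 * np.eye(4))
        x1s, b21dot = conditional_design(x1, x2, b)
        np.testing.assert_array_equal(x1s, x1)
        np.testing.assert_array_equal(b21dot, b.B22)

    def test_perfect_correlation_degenerates_with_warning(self, rng):
        x1 = rng.standard_normal((6, 2))
        x2 = rng.standard_normal((6, 2))
        b = EffectCovariance(B11=np.eye(2), B22=np.eye(2), B12=np.eye(2))
        with pytest.warns(RuntimeWarning, match="singular"):
            _, b21dot = conditional_design(x1, x2, b)
        assert np.abs(b21dot).max() < 1e-12

    def test_schur_complement_matches_brute_force(self, rng):
        b = _random_pd_joint(rng, 3, 5)
        x1 = rng.standard_normal((10, 3))
        x2 = rng.standard_normal((10, 5))
        _, b21dot = conditional_design(x1, x2, b)
        oracle = b.B22 - b.B21 @ np.linalg.inv(b.B11) @ b.B12
        assert np.abs(b21dot - oracle).max() < 1e-10

    def test_general_b11_uses_regression_coefficient(self, rng):
        b = _random_pd_joint(rng, 2, 3)
        x1 = rng.standard_normal((8, 2))
        x2 = rng.standard_normal((8, 3))
        x1s, _ = conditional_design(x1, x2, b)
        gamma = b.B21 @ np.linalg.inv(b.B11)
        np.testing.assert_allclose(x1s, x1 + x2 @ gamma, atol=1e-12)


class TestConditionalGlsAndBlup:
    def test_reduces_to_uncorrelated_gls(self, rng):
        """With B12 = 0 the conditional GLS equals the plain V2-path BLUE."""
        n, p1, p2 = 12, 2, 20
        codes = rng.integers(0, 3, size=(n, p1 + p2)).astype(float)
        geno = GenotypeMatrix(
            [f"s{i}" for i in range(n)], [f"m{j}" for j in range(p1 + p2)], codes
        )
        y = rng.standard_normal(n)
        vc = VarianceComponents(0.6, 1.4)
        part = geno.partition(list(range(p1)))
        x1, x2 = geno.split(part)
        b = EffectCovariance(
            B11=0.6 * np.eye(p1), B22=0.6 * np.eye(p2), R=1.4 * np.eye(n)
        )
        x1s, b21dot = conditional_design(x1, x2, b)
        est = conditional_gls(x1s, x2, b21dot, b.R, y)
        model = build_covariances(geno, part, vc)
        np.testing.assert_allclose(
            est, gls_estimate(x1, np.linalg.inv(model.V2), y), atol=1e-10
        )

    def test_v2_star_assembly_matches_dense_oracle(self, rng):
        b = _random_pd_joint(rng, 2, 4)
        b = EffectCovariance(B11=b.B11, B22=b.B22, B12=b.B12, R=np.eye(9))
        x1 = rng.standard_normal((9, 2))
        x2 = rng.standard_normal((9, 4))
        y = rng.standard_normal(9)
        res = fit_conditional(x1, x2, b, y)
        oracle = x2 @ res.B_2dot1 @ x2.T + b.R
        assert np.abs(res.V2_star - oracle).max() < 1e-12

    def test_noise_free_limit_recovers_beta1(self, rng):
        b = _random_pd_joint(rng, 2, 4)
        x1 = rng.standard_normal((20, 2))
        x2 = rng.standard_normal((20, 4))
        beta1 = np.array([1.5, -0.7])
        x1s, b21dot = conditional_design(x1, x2, b)
        y = x1s @ beta1
        est = conditional_gls(x1s, x2, 1e-10 * b21dot, 1e-10 * np.eye(20), y)
        assert np.abs(est - beta1).max() < 1e-4

    def test_blup_delta_zero_for_exact_fit_and_zero_covariance(self, rng):
        b = _random_pd_joint(rng, 1, 3)
        x1 = rng.standard_normal((8, 1))
        x2 = rng.standard_normal((8, 3))
        x1s, b21dot = conditional_design(x1, x2, b)
        beta1 = np.array([2.0])
        y = (x1s @ beta1).ravel()
        v2s_inv = np.linalg.inv(x2 @ b21dot @ x2.T + np.eye(8))
        delta = conditional_blup_delta(x2, b21dot, v2s_inv, y, x1s, beta1)
        assert np.abs(delta).max() < 1e-12
        delta0 = conditional_blup_delta(
            x2, np.zeros((3, 3)), v2s_inv, rng.standard_normal(8), x1s, beta1
        )
        assert np.all(delta0 == 0)

    def test_blup_delta_matches_dense_evaluation(self, rng):
        b = _random_pd_joint(rng, 2, 4)
        b = EffectCovariance(B11=b.B11, B22=b.B22, B12=b.B12, R=np.eye(10))
        x1 = rng.standard_normal((10, 2))
        x2 = rng.standard_normal((10, 4))
        y = rng.standard_normal(10)
        res = fit_conditional(x1, x2, b, y)
        v2s_inv = np.linalg.inv(res.V2_star)
        oracle = res.B_2dot1 @ x2.T @ v2s_inv @ (y - res.X1_star @ res.beta1_est)
        assert np.abs(res.blup_delta - oracle).max() < 1e-10


class TestSignalDecomposition:
    def test_trivial_zeros(self, rng):
        x1 = rng.standard_normal((5, 2))
        x2 = rng.standard_normal((5, 3))
        d, i = signal_decomposition(x1, x2, np.zeros((3, 2)), np.ones(2))
        assert np.all(i == 0)
        d, i = signal_decomposition(x1, x2, rng.standard_normal((3, 2)), np.zeros(2))
        assert np.all(d == 0) and np.all(i == 0)

    def test_sum_equals_effective_design_signal(self, rng):
        # with unit tested-set prior variance B11 = I
        p1, p2 = 2, 4
        b21 = rng.standard_normal((p2, p1)) * 0.1
        b = EffectCovariance(B11=np.eye(p1), B22=np.eye(p2) + b21 @ b21.T, B12=b21.T)
        x1 = rng.standard_normal((7, p1))
        x2 = rng.standard_normal((7, p2))
        beta1 = rng.standard_normal(p1)
        x1s, _ = conditional_design(x1, x2, b)
        d, i = signal_decomposition(x1, x2, b.B21, beta1)
        assert np.abs((d + i) - x1s @ beta1).max() < 1e-12


def test_conditional_expectation_regression_recovered():
    """Empirical regression of beta2 on beta1 recovers B21 B11^-1."""
    rng = np.random.default_rng(99)
    p1, p2 = 1, 2
    b12 = np.array([[0.6, -0.3]])
    b = EffectCovariance(B11=np.eye(p1) * 2.0, B22=np.eye(p2), B12=b12)
    draws = np.array(
        [
            np.concatenate(simulate_effects(p1, p2, 1.0, block_cov=b, seed=s))
            for s in range(5000)
        ]
    )
    beta1, beta2 = draws[:, :p1], draws[:, p1:]
    coef = np.linalg.lstsq(beta1, beta2, rcond=None)[0].T  # p2 x p1
    expected = b.B21 @ np.linalg.inv(b.B11)
    # Monte-Carlo error of a regression slope at n=5000
    assert np.abs(coef - expected).max() < 3 * np.sqrt(1.0 / (2.0 * 5000)) * 3


class TestConditionalEstimator:
    def test_fit_and_signal_paths(self, rng):
        n, p1, p2 = 20, 1, 6
        codes = rng.integers(0, 3, size=(n, p1 + p2)).astype(float)
        y = rng.standard_normal(n)
        b12 = np.zeros((p1, p2))
        b12[0, 0] = 0.5
        b = EffectCovariance(B11=np.eye(p1), B22=np.eye(p2), B12=b12)
        est = ConditionalGLS(tested=(0,), effect_cov=b, sigma_e2=1.0)
        est.fit(codes, y)
        total = est.direct_signal_ + est.indirect_signal_
        np.testing.assert_allclose(total, est.result_.X1_star @ est.coef_, atol=1e-10)
        assert est.predict(codes).shape == (n,)
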