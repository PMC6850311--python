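"""Henderson's MME: assembly, zero-BLUP, reduced model, correlated blocks."""

import numpy as np
import pytest

from gblue.covariance import build_covariances
from gblue.datatypes import EffectCovariance, VarianceComponents
from gblue.exceptions import ConfigurationError
from gblue.gls import gls_estimate
from gblue.mme import (
    HendersonMME,
    build_mme,
    reduced_mme,
    solve_mme,
    solve_mme_correlated,
)


def _random_instance(rng, n=10, p1=2, p2=4):
    x1 = rng.integers(0, 3, size=(n, p1)).astype(float)
    x2 = rng.integers(0, 3, size=(n, p2)).astype(float)
    y = rng.standard_normal(n)
    return x1, x2, y


class TestAssembly:
    def test_scalar_iid_blocks_as_printed(self, rng):
        x1, x2, y = _random_instance(rng)
        vc = VarianceComponents(0.5, 1.0)
        system = build_mme(x1, x2, y, vc, treatment="scalar-iid")
        a = system.matrix()
        p1, p2 = 2, 4
        lam = vc.lam
        np.testing.assert_array_equal(a[:p1, :p1], x1.T @ x1)
        np.testing.assert_array_equal(a[:p1, p1 : 2 * p1], x1.T @ x1)
        np.testing.assert_array_equal(a[p1 : 2 * p1, :p1], x1.T @ x1)
        np.testing.assert_array_equal(
            a[p1 : 2 * p1, p1 : 2 * p1], x1.T @ x1 + lam * np.eye(p1)
        )
        np.testing.assert_array_equal(a[2 * p1 :, 2 * p1 :], x2.T @ x2 + lam * np.eye(p2))
        np.testing.assert_array_equal(system.rhs()[:p1], x1.T @ y)
        np.testing.assert_array_equal(system.rhs()[2 * p1 :], x2.T @ y)

    def test_block_system_assembled_from_printed_formulas(self, rng):
        """Entry-by-entry oracle: independent assembly from the block formulas."""
        n, p1, p2 = 8, 2, 3
        x1, x2, y = _random_instance(rng, n, p1, p2)
        r = np.diag(rng.uniform(0.5, 2.0, size=n))
        b = EffectCovariance(B11=0.7 * np.eye(p1), B22=1.3 * np.eye(p2), R=r)
        system = build_mme(x1, x2, y, b, treatment="block-independent")
        rinv = np.linalg.inv(r)
        oracle = np.block(
            [
                [x1.T @ rinv @ x1, x1.T @ rinv @ x1, x1.T @ rinv @ x2],
                [x1.T @ rinv @ x1, x1.T @ rinv @ x1 + np.eye(p1) / 0.7, x1.T @ rinv @ x2],
                [x2.T @ rinv @ x1, x2.T @ rinv @ x1, x2.T @ rinv @ x2 + np.eye(p2) / 1.3],
            ]
        )
        assert np.abs(system.matrix() - oracle).max() < 1e-10

    def test_correlated_with_zero_b12_equals_independent(self, rng):
        x1, x2, y = _random_instance(rng)
        r = np.eye(10)
        b0 = EffectCovariance(B11=np.eye(2), B22=np.eye(4), R=r)
        b1 = EffectCovariance(B11=np.eye(2), B22=np.eye(4), B12=np.zeros((2, 4)), R=r)
        s0 = build_mme(x1, x2, y, b0, treatment="block-independent")
        s1 = build_mme(x1, x2, y, b1, treatment="block-correlated")
        np.testing.assert_allclose(s0.matrix(), s1.matrix(), atol=1e-12)

    def test_zero_sigma_beta2_unsupported(self, rng):
        x1, x2, y = _random_instance(rng)
        with pytest.raises(ConfigurationError, match="GLS path"):
            build_mme(x1, x2, y, VarianceComponents(0.0, 1.0), treatment="scalar-iid")


class TestScalarSolve:
    def test_blup1_is_zero(self, small_instance):
        geno, pheno, part, vc, _ = small_instance
        x1, x2 = geno.split(part)
        system = build_mme(x1, x2, pheno.values, vc, treatment="scalar-iid")
        for method in ("reduce", "direct"):
            sol = solve_mme(system, method=method)
            assert np.abs(sol.blup1).max() < 1e-8

    def test_alpha_matches_gls_path(self, small_instance):
        geno, pheno, part, vc, _ = small_instance
        x1, x2 = geno.split(part)
        system = build_mme(x1, x2, pheno.values, vc, treatment="scalar-iid")
        sol = solve_mme(system, method="direct")
        model = build_covariances(geno, part, vc)
        gls = gls_estimate(x1, model.v12_inverse(), pheno.values)
        assert np.abs(sol.alpha_hat - gls).max() < 1e-8

    def test_blup2_matches_classical_formula(self, small_instance):
        geno, pheno, part, vc, _ = small_instance
        x1, x2 = geno.split(part)
        system = build_mme(x1, x2, pheno.values, vc, treatment="scalar-iid")
        sol = solve_mme(system)
        model = build_covariances(geno, part, vc)
        v2_inv = model.v2_inverse()
        oracle = vc.sigma_beta2 * x2.T @ (v2_inv @ (pheno.values - x1 @ sol.alpha_hat))
        assert np.abs(sol.blup2 - oracle).max() < 1e-8

    def test_direct_and_reduce_agree(self, small_instance):
        geno, pheno, part, vc, _ = small_instance
        x1, x2 = geno.split(part)
        system = build_mme(x1, x2, pheno.values, vc, treatment="scalar-iid")
        a = solve_mme(system, method="reduce")
        b = solve_mme(system, method="direct")
        for attr in ("alpha_hat", "blup1", "blup2"):
            assert np.abs(getattr(a, attr) - getattr(b, attr)).max() < 1e-8

    def test_normal_equation_residual_contract(self, small_instance):
        geno, pheno, part, vc, _ = small_instance
        x1, x2 = geno.split(part)
        system = build_mme(x1, x2, pheno.values, vc, treatment="scalar-iid")
        assert solve_mme(system).residual < 1e-8


class TestCorrelatedSolve:
    def _correlated_instance(self, rng, rho=0.8, n=12, p1=2, p2=5):
        x1, x2, y = _random_instance(rng, n, p1, p2)
        b12 = np.zeros((p1, p2))
        for i in range(p1):
            b12[i, i] = rho
        r = np.eye(n)
        b = EffectCovariance(B11=np.eye(p1), B22=np.eye(p2), B12=b12, R=r)
        return x1, x2, y, b

    def test_coupling_identity(self, rng):
        x1, x2, y, b = self._correlated_instance(rng)
        system = build_mme(x1, x2, y, b, treatment="block-correlated")
        sol = solve_mme_correlated(system, method="direct")
        assert np.abs(sol.blup1 + sol.coupling @ sol.blup2).max() < 1e-8
        assert np.abs(sol.blup1).max() > 0  # genuinely non-null

    def test_invariance_fails_under_correlation(self, rng):
        x1, x2, y, b = self._correlated_instance(rng, rho=0.8)
        b0 = EffectCovariance(B11=b.B11, B22=b.B22, R=b.R)
        sol_c = solve_mme_correlated(
            build_mme(x1, x2, y, b, treatment="block-correlated"), method="direct"
        )
        sol_0 = solve_mme(
            build_mme(x1, x2, y, b0, treatment="block-independent"), method="direct"
        )
        assert np.abs(sol_0.blup1).max() < 1e-8
        assert np.abs(sol_c.alpha_hat - sol_0.alpha_hat).max() > 1e-4

    def test_alpha_matches_dense_gls_under_full_covariance(self, rng):
        """MME fixed effect equals GLS under V = [X1 X2] B [X1 X2]' + R."""
        x1, x2, y, b = self._correlated_instance(rng)
        system = build_mme(x1, x2, y, b, treatment="block-correlated")
        sol = solve_mme_correlated(system, method="direct")
        w = np.hstack([x1, x2])
        v = w @ b.joint() @ w.T + b.R
        oracle = gls_estimate(x1, np.linalg.inv(v), y)
        assert np.abs(sol.alpha_hat - oracle).max() < 1e-8

    def test_requires_correlated_treatment(self, rng):
        x1, x2, y = _random_instance(rng)
        system = build_mme(x1, x2, y, VarianceComponents(1.0, 1.0), treatment="scalar-iid")
        with pytest.raises(ConfigurationError):
            solve_mme_correlated(system)


class TestReducedMme:
    def test_agrees_with_full_double_counting_solve(self, rng):
        x1, x2, y = _random_instance(rng, n=12, p1=2, p2=5)
        r = np.eye(12)
        b = EffectCovariance(B11=np.eye(2), B22=np.eye(5), R=r)
        full = solve_mme(build_mme(x1, x2, y, b, treatment="block-independent"))
        alpha, blup2 = reduced_mme(x1, x2, y, b)
        assert np.abs(full.alpha_hat - alpha).max() < 1e-8
        assert np.abs(full.blup2 - blup2).max() < 1e-8

    def test_vanishing_prior_variance_limit(self, rng):
        x1, x2, y = _random_instance(rng, n=12, p1=2, p2=5)
        r = np.eye(12)
        b = EffectCovariance(B11=np.eye(2), B22=1e-8 * np.eye(5), R=r)
        alpha, blup2 = reduced_mme(x1, x2, y, b)
        assert np.abs(blup2).max() < 1e-3
        ols = gls_estimate(x1, np.linalg.inv(r), y)
        assert np.abs(alpha - ols).max() < 1e-3

    def test_zero_background_column_toy(self):
        x1 = np.array([[1.0], [2.0], [0.0]])
        x2 = np.zeros((3, 1))
        y = np.array([1.0, 2.0, 3.0])
        b = EffectCovariance(B11=np.eye(1), B22=np.eye(1), R=np.eye(3))
        alpha, blup2 = reduced_mme(x1, x2, y, b)
        assert blup2 == pytest.approx([0.0])
        assert alpha == pytest.approx(gls_estimate(x1, np.eye(3), y))


class TestHendersonEstimator:
    def test_fit_scalar_and_predict(self, small_instance):
        geno, pheno, part, vc, _ = small_instance
        est = HendersonMME(tested=(0, 1), sigma_beta2=vc.sigma_beta2, sigma_e2=vc.sigma_e2)
        est.fit(geno.codes, pheno.values)
        assert est.treatment_ == "scalar-iid"
        assert np.abs(est.blup1_).max() < 1e-8
        x1, x2 = geno.split(part)
        fitted = est.predict(geno.codes)
        np.testing.assert_allclose(
            fitted, x1 @ (est.alpha_ + est.blup1_) + x2 @ est.blup2_
        )

    def test_fit_selects_correlated_treatment(self, rng):
        n, p1, p2 = 15, 1, 9
        codes = rng.integers(0, 3, size=(n, p1 + p2)).astype(float)
        y = rng.standard_normal(n)
        b12 = np.zeros((p1, p2))
        b12[0, 0] = 0.8
        b = EffectCovariance(B11=np.eye(p1), B22=np.eye(p2), B12=b12)
        est = HendersonMME(tested=(0,), sigma_e2=1.0, effect_cov=b)
        est.fit(codes, y)
        assert est.treatment_ == "block-correlated"
        assert np.abs(est.blup1_).max() > 0
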