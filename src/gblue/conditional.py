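"""Conditional model for tested effects correlated with the background.

When the tested effects β1 are fixed by conditioning but covary with the
background effects (Cov(β1, β2') = B12 ≠ 0), fixing β1 shifts the
distribution of β2. Under joint normality β2 = B21B11⁻¹ β1 + δ with
δ ~ N(0, B2.1), B2.1 = B22 − B21B11⁻¹B12 (the Schur complement), and the
model becomes

    y = (X1 + X2 B21B11⁻¹) β1 + X2 δ + e = X1* β1 + X2 δ + e,

with phenotypic covariance V2* = X2 B2.1 X2' + R. The total signal of β1
splits into a direct path X1β1 and an indirect path X2B21B11⁻¹β1 mediated
by the effect covariance — over and above any LD encoded in the columns
of X.

Note: the common presentation writes β2 = B21β1 + δ, which presumes unit
prior variance for the tested set (B11 = I). This module uses the general
regression coefficient B21B11⁻¹ and reduces to that expression when
B11 = I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, validate_data

from ._linalg import spd_inverse, spd_solve, symmetrize
from .datatypes import EffectCovariance, GenotypeMatrix
from .exceptions import ConfigurationError, DimensionError
from .gls import gls_estimate

__all__ = [
    "ConditionalResult",
    "conditional_design",
    "conditional_gls",
    "conditional_blup_delta",
    "signal_decomposition",
    "ConditionalGLS",
]


@dataclass
class ConditionalResult:
    """Outputs of a conditional-model fit."""

    X1_star: np.ndarray
    B_2dot1: np.ndarray
    V2_star: np.ndarray
    beta1_est: np.ndarray
    blup_delta: np.ndarray
    direct_signal: np.ndarray
    indirect_signal: np.ndarray


def conditional_design(
    x1: np.ndarray, x2: np.ndarray, b: EffectCovariance
) -> tuple[np.ndarray, np.ndarray]:
    """Effective design X1* = X1 + X2·B21B11⁻¹ and conditional covariance B2.1.

    B2.1 = B22 − B21B11⁻¹B12 is the Schur complement of B11 in the joint
    effect covariance. A (numerically) singular B2.1 — e.g. perfectly
    correlated blocks — is accepted with a warning; V2* stays positive
    definite through R.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] != b.p1 or x2.shape[1] != b.p2:
        raise DimensionError(
            f"designs ({x1.shape[1]},{x2.shape[1]}) do not match covariance blocks "
            f"({b.p1},{b.p2})"
        )
    try:
        b11_inv_b12 = np.linalg.solve(b.B11, b.B12)  # B11^-1 B12, p1 x p2
    except np.linalg.LinAlgError as err:
        raise ConfigurationError(f"B11 is singular: {err}") from err
    gamma = b11_inv_b12.T  # B21 B11^-1, p2 x p1
    x1_star = x1 + x2 @ gamma
    b_2dot1 = symmetrize(b.B22 - b.B21 @ b11_inv_b12)
    ev_min = np.linalg.eigvalsh(b_2dot1).min()
    scale = max(np.abs(np.diag(b.B22)).max(), 1.0)
    if ev_min <= 1e-10 * scale:
        warnings.warn(
            f"conditional covariance B2.1 is numerically singular (min eigenvalue "
            f"{ev_min:.3e}): the background effects are (near-)perfectly determined "
            "by the tested effects",
            RuntimeWarning,
            stacklevel=2,
        )
    return x1_star, b_2dot1


def conditional_gls(
    x1_star: np.ndarray,
    x2: np.ndarray,
    b_2dot1: np.ndarray,
    r: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """GLS of the tested effects under the conditional model.

    Returns (X1*'V2*⁻¹X1*)⁻¹ X1*'V2*⁻¹ y with V2* = X2·B2.1·X2' + R.
    """
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    v2_star = symmetrize(x2 @ b_2dot1 @ x2.T + r)
    return gls_estimate(x1_star, spd_inverse(v2_star), y)


def conditional_blup_delta(
    x2: np.ndarray,
    b_2dot1: np.ndarray,
    v2_star_inv: np.ndarray,
    y: np.ndarray,
    x1_star: np.ndarray,
    beta1_est: np.ndarray,
) -> np.ndarray:
    """BLUP of δ: the background-marker signal net of the tested effects.

    BLUP(δ) = B2.1·X2'·V2*⁻¹·(y − X1*·β1), using Cov(δ, y') = B2.1·X2'.
    Predicts the effect of the background markers on phenotypes in the
    absence of genetic variation at the tested loci.
    """
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    resid = np.asarray(y, dtype=float).ravel() - np.atleast_2d(x1_star) @ np.asarray(
        beta1_est, dtype=float
    ).ravel()
    return b_2dot1 @ (x2.T @ (v2_star_inv @ resid))


def signal_decomposition(
    x1: np.ndarray, x2: np.ndarray, b21: np.ndarray, beta1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Split the total signal of β1 into direct and indirect paths.

    direct = X1·β1; indirect = X2·B21·β1. With unit tested-set prior
    variance (B11 = I) their sum is X1*·β1.
    """
    beta1 = np.asarray(beta1, dtype=float).ravel()
    direct = np.atleast_2d(np.asarray(x1, dtype=float)) @ beta1
    indirect = np.atleast_2d(np.asarray(x2, dtype=float)) @ (
        np.atleast_2d(np.asarray(b21, dtype=float)) @ beta1
    )
    return direct, indirect


def fit_conditional(
    x1: np.ndarray, x2: np.ndarray, b: EffectCovariance, y: np.ndarray
) -> ConditionalResult:
    """Full conditional-model fit: design, GLS, BLUP(δ) and signal split."""
    if b.R is None:
        raise ConfigurationError("conditional model needs a residual covariance R")
    x1_star, b_2dot1 = conditional_design(x1, x2, b)
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    v2_star = symmetrize(x2 @ b_2dot1 @ x2.T + b.R)
    v2_star_inv = spd_inverse(v2_star)
    beta1_est = gls_estimate(x1_star, v2_star_inv, y)
    delta = conditional_blup_delta(x2, b_2dot1, v2_star_inv, y, x1_star, beta1_est)
    gamma = np.linalg.solve(b.B11, b.B12).T  # B21 B11^-1
    direct = np.atleast_2d(np.asarray(x1, dtype=float)) @ beta1_est
    indirect = x2 @ (gamma @ beta1_est)
    return ConditionalResult(
        X1_star=x1_star,
        B_2dot1=b_2dot1,
        V2_star=v2_star,
        beta1_est=beta1_est,
        blup_delta=delta,
        direct_signal=direct,
        indirect_signal=indirect,
    )


class ConditionalGLS(BaseEstimator):
    """GLS of a tested marker set whose effects covary with the background.

    ``fit(X, y)`` partitions the genotype matrix by ``tested``, builds the
    effective design X1* = X1 + X2·B21B11⁻¹ and conditional covariance
    V2* = X2·B2.1·X2' + R, and estimates β1 together with BLUP(δ) and the
    direct/indirect signal decomposition.

    Parameters
    ----------
    tested : sequence of int
        Column indices of the tested marker set.
    effect_cov : EffectCovariance
        Joint effect covariance (B11, B22, B12) and optionally R.
    sigma_e2 : float
        Used to default R = I·σe² when ``effect_cov.R`` is absent.

    Attributes
    ----------
    coef_ : β1 estimate under the conditional model.
    blup_delta_ : BLUP of the conditional background effects δ.
    direct_signal_, indirect_signal_ : per-sample signal paths X1β1 and
        X2·B21B11⁻¹·β1.
    result_ : the full :class:`ConditionalResult`.
    """

    def __init__(
        self,
        tested=(0,),
        effect_cov: EffectCovariance | None = None,
        sigma_e2: float = 1.0,
    ):
        self.tested = tested
        self.effect_cov = effect_cov
        self.sigma_e2 = sigma_e2

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=2)
        if self.effect_cov is None:
            raise ConfigurationError("ConditionalGLS requires an effect_cov")
        geno = GenotypeMatrix(
            sample_ids=[str(i) for i in range(X.shape[0])],
            marker_ids=[str(j) for j in range(X.shape[1])],
            codes=X,
        )
        part = geno.partition(np.asarray(self.tested, dtype=int))
        x1, x2 = geno.split(part)
        b = self.effect_cov
        if b.R is None:
            b = EffectCovariance(
                B11=b.B11, B22=b.B22, B12=b.B12, R=self.sigma_e2 * np.eye(X.shape[0])
            )
        res = fit_conditional(x1, x2, b, y)
        self.result_ = res
        self.coef_ = res.beta1_est
        self.blup_delta_ = res.blup_delta
        self.direct_signal_ = res.direct_signal
        self.indirect_signal_ = res.indirect_signal
        return self

    def predict(self, X):
        """Conditional fitted signal X1*·β1 + X2·BLUP(δ) for new samples."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        idx = np.asarray(self.tested, dtype=int)
        mask = np.ones(X.shape[1], dtype=bool)
        mask[idx] = False
        b = self.effect_cov
        gamma = np.linalg.solve(b.B11, b.B12).T
        x1_star = X[:, idx] + X[:, mask] @ gamma
        return x1_star @ self.coef_ + X[:, mask] @ self.blup_delta_
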