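"""BLUE of tested marker effects and Wald testing.

The generalized least-squares estimator of the tested-set effects is

    b̂ = (X1'V⁻¹X1)⁻¹ X1'V⁻¹ y,

and it is *invariant* to whether V is V2 (tested markers excluded from the
random part) or V12 (all markers in the random part), provided the
variance components are held fixed and the tested effects are uncorrelated
with the background effects. The sampling covariance, however, must be
taken under V2; given the V12 path it is recovered by the down-date

    Var(b̂) = (X1'V2⁻¹X1)⁻¹ = (X1'V12⁻¹X1)⁻¹ − I·σβ².

Using (X1'V12⁻¹X1)⁻¹ directly overstates uncertainty by exactly σβ² on
each diagonal element — the "naive" covariance reported alongside the
adjusted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted, validate_data

from ._linalg import assert_full_column_rank, spd_solve, symmetrize
from .covariance import build_covariances, center_codes
from .datatypes import GenotypeMatrix, VarianceComponents
from .exceptions import DimensionError, NumericalDegeneracyError

__all__ = [
    "BlueResult",
    "gls_estimate",
    "adjusted_variance",
    "wald_test",
    "MarkerSetGLS",
]

#: relative eigenvalue tolerance when declaring a covariance non-PD
_PD_RTOL = 1e-10


@dataclass
class BlueResult:
    """BLUE of a tested marker set with adjusted and naive covariance."""

    estimate: np.ndarray
    cov_adjusted: np.ndarray
    cov_naive: np.ndarray
    wald_stat: float
    df: int
    p_value: float
    structure_used: str  # "V2" or "V12"

    @property
    def se_adjusted(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_adjusted))

    @property
    def se_naive(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_naive))


def gls_estimate(x1: np.ndarray, v_inv: np.ndarray, y: np.ndarray) -> np.ndarray:
    """GLS/BLUE of the tested-set effects: (X1'V⁻¹X1)⁻¹ X1'V⁻¹ y.

    ``v_inv`` may come from V2 or from V12; by the invariance property the
    result is the same. A QR rank check on X1 precedes the solve so a rank
    deficiency fails with named columns rather than a singular-matrix error.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x1.shape[0] != y.size or v_inv.shape[0] != y.size:
        raise DimensionError(
            f"non-conformable GLS inputs: X1 {x1.shape}, V_inv {v_inv.shape}, y ({y.size},)"
        )
    assert_full_column_rank(x1, "X1")
    xtv = x1.T @ v_inv
    return spd_solve(xtv @ x1, xtv @ y)


def adjusted_variance(
    x1: np.ndarray, v12_inv: np.ndarray, sigma_beta2: float
) -> np.ndarray:
    """Sampling covariance of the BLUE under V2, computed from the V12 path.

    Returns (X1'V12⁻¹X1)⁻¹ − I·σβ², which equals (X1'V2⁻¹X1)⁻¹ exactly.

    Raises
    ------
    NumericalDegeneracyError
        If the result is not positive definite within tolerance — the
        signature of a near-singular down-date (e.g. extreme collinearity
        in X1).
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    assert_full_column_rank(x1, "X1")
    info = symmetrize(x1.T @ v12_inv @ x1)
    naive = spd_solve(info, np.eye(x1.shape[1]))
    adj = symmetrize(naive - sigma_beta2 * np.eye(x1.shape[1]))
    ev = np.linalg.eigvalsh(adj)
    scale = max(abs(np.diag(naive)).max(), 1.0)
    if ev.min() <= _PD_RTOL * scale:
        raise NumericalDegeneracyError(
            "adjusted covariance (X1'V12^-1 X1)^-1 - I*sigma_beta2 is not positive "
            f"definite (min eigenvalue {ev.min():.3e}); the covariance down-date is "
            "numerically degenerate for this tested set"
        )
    return adj


def wald_test(result: "BlueResult | tuple[np.ndarray, np.ndarray]") -> tuple[float, float]:
    """Wald chi-square test of nullity of the tested-set effects.

    Accepts a :class:`BlueResult` (uses its adjusted covariance) or an
    ``(estimate, covariance)`` pair. Returns ``(statistic, p_value)`` with
    the p-value from the upper tail of chi-square with p1 degrees of
    freedom — variance components are treated as known, so no small-sample
    t/F correction applies.
    """
    if isinstance(result, BlueResult):
        est, cov = result.estimate, result.cov_adjusted
    else:
        est, cov = result
    est = np.asarray(est, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    ev = np.linalg.eigvalsh(symmetrize(cov))
    if ev.min() <= 0:
        raise NumericalDegeneracyError(
            f"Wald covariance not positive definite (min eigenvalue {ev.min():.3e})"
        )
    stat = float(est @ spd_solve(cov, est))
    p_value = float(stats.chi2.sf(stat, df=est.size))
    return stat, p_value


def blue_for_set(
    x1: np.ndarray,
    v12_inv: np.ndarray,
    y: np.ndarray,
    sigma_beta2: float,
) -> BlueResult:
    """BLUE + adjusted/naive covariance + Wald test via the reusable V12⁻¹ path."""
    est = gls_estimate(x1, v12_inv, y)
    info = symmetrize(np.atleast_2d(x1).T @ v12_inv @ np.atleast_2d(x1))
    naive = symmetrize(spd_solve(info, np.eye(est.size)))
    adj = adjusted_variance(x1, v12_inv, sigma_beta2)
    stat, p = wald_test((est, adj))
    return BlueResult(
        estimate=est,
        cov_adjusted=adj,
        cov_naive=naive,
        wald_stat=stat,
        df=est.size,
        p_value=p,
        structure_used="V12",
    )


def blue_for_set_v2(x1: np.ndarray, v2_inv: np.ndarray, y: np.ndarray, sigma_beta2: float) -> BlueResult:
    """BLUE computed entirely under V2 (the brute-force per-set strategy)."""
    est = gls_estimate(x1, v2_inv, y)
    info = symmetrize(np.atleast_2d(x1).T @ v2_inv @ np.atleast_2d(x1))
    adj = symmetrize(spd_solve(info, np.eye(est.size)))
    naive = symmetrize(adj + sigma_beta2 * np.eye(est.size))
    stat, p = wald_test((est, adj))
    return BlueResult(
        estimate=est,
        cov_adjusted=adj,
        cov_naive=naive,
        wald_stat=stat,
        df=est.size,
        p_value=p,
        structure_used="V2",
    )


class MarkerSetGLS(BaseEstimator):
    """BLUE of a tested marker set under a genomic mixed-model covariance.

    Scikit-learn style estimator: ``fit(X, y)`` takes the full n×p genotype
    code matrix and phenotypes; the markers in ``tested`` form the fixed
    set X1 and all remaining markers form the random background X2 with
    i.i.d. N(0, σβ²) effects and N(0, σe²) residuals.

    Parameters
    ----------
    tested : sequence of int
        Column indices of the tested marker set (X1).
    sigma_beta2, sigma_e2 : float
        Known variance components; never re-estimated.
    structure : {"V12", "V2"}
        Which covariance structure to compute under. The point estimate is
        identical either way; "V12" uses the reusable all-marker inverse
        with the σβ² covariance down-date, "V2" rebuilds the
        background-only covariance.
    center : bool
        Column-center the genotype codes before building covariances.

    Attributes
    ----------
    coef_ : (p1,) BLUE of the tested effects.
    cov_ : (p1, p1) adjusted sampling covariance (under V2) — use this for
        inference.
    cov_naive_ : (p1, p1) the V12-path covariance before adjustment.
    wald_, p_value_, df_ : Wald test of joint nullity of the tested set.
    result_ : the full :class:`BlueResult`.
    """

    def __init__(
        self,
        tested=(0,),
        sigma_beta2: float = 1.0,
        sigma_e2: float = 1.0,
        structure: str = "V12",
        center: bool = False,
    ):
        self.tested = tested
        self.sigma_beta2 = sigma_beta2
        self.sigma_e2 = sigma_e2
        self.structure = structure
        self.center = center

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_min_features=2)
        if self.structure not in ("V12", "V2"):
            raise ValueError(f"structure must be 'V12' or 'V2', got {self.structure!r}")
        geno = GenotypeMatrix(
            sample_ids=[str(i) for i in range(X.shape[0])],
            marker_ids=[str(j) for j in range(X.shape[1])],
            codes=X,
        )
        part = geno.partition(np.asarray(self.tested, dtype=int))
        vc = VarianceComponents(self.sigma_beta2, self.sigma_e2)
        model = build_covariances(geno, part, vc, center=self.center)
        x1 = center_codes(X[:, part.tested]) if self.center else X[:, part.tested]
        if self.structure == "V12":
            res = blue_for_set(x1, model.v12_inverse(), y, vc.sigma_beta2)
        else:
            res = blue_for_set_v2(x1, model.v2_inverse(), y, vc.sigma_beta2)
        self.result_ = res
        self.coef_ = res.estimate
        self.cov_ = res.cov_adjusted
        self.cov_naive_ = res.cov_naive
        self.wald_ = res.wald_stat
        self.p_value_ = res.p_value
        self.df_ = res.df
        return self

    def predict(self, X):
        """Fixed-part fitted values X1·coef_ for new samples (same marker columns)."""
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        idx = np.asarray(self.tested, dtype=int)
        x1 = center_codes(X[:, idx]) if self.center else X[:, idx]
        return x1 @ self.coef_
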