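"""Phenotypic covariance structures for marker-set testing.

Two structures are central. With the tested markers' effects treated as
fixed and excluded from the random part,

    V2 = X2 X2' σβ² + I σe²,

and with every marker contributing to the random part,

    V12 = X1 X1' σβ² + X2 X2' σβ² + I σe².

The rank-p1 gap V12 − V2 = X1 X1' σβ² is what the Woodbury down-date
exploits: V2⁻¹ is obtained from V12⁻¹ with a p1×p1 solve, so the expensive
all-marker inverse is computed once per scan while the tested set changes.

The marker cross-products are also exposed in genomic-relationship form:
S12 = G12·σg² with G12 = (X1X1' + X2X2')/p, σg² = p·σβ², and
S2 = G2·σg'² with G2 = X2X2'/p2, σg'² = p2·σβ².
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from ._linalg import spd_inverse, symmetrize
from .datatypes import GenotypeMatrix, MarkerPartition, VarianceComponents
from .exceptions import DimensionError, SingularDowndateError

__all__ = [
    "CovarianceModel",
    "build_similarity",
    "build_covariances",
    "woodbury_downdate_inverse",
    "center_codes",
]

logger = logging.getLogger(__name__)

#: jitter scale factor applied to the diagonal (times σe²) if a Cholesky
#: factorization of V2/V12 fails despite σe² > 0
JITTER_FACTOR = 1e-10


@dataclass
class CovarianceModel:
    """Similarity matrices, phenotypic covariances and GRM scalings for one partition."""

    S2: np.ndarray
    S12: np.ndarray
    V2: np.ndarray
    V12: np.ndarray
    G2: np.ndarray
    G12: np.ndarray
    sigma_g2_all: float
    sigma_g2_bg: float
    vc: VarianceComponents

    def v12_inverse(self) -> np.ndarray:
        """Explicit V12⁻¹, the object reused across every tested set of a scan."""
        return spd_inverse(self.V12, jitter=JITTER_FACTOR * self.vc.sigma_e2)

    def v2_inverse(self) -> np.ndarray:
        return spd_inverse(self.V2, jitter=JITTER_FACTOR * self.vc.sigma_e2)


def center_codes(x: np.ndarray) -> np.ndarray:
    """Column-center genotype codes (subtract twice the allele frequency).

    Common GRM practice; optional here because every identity implemented
    in this package holds for arbitrary real codes.
    """
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=0, keepdims=True)


def build_similarity(x_sub: np.ndarray, sigma_beta2: float, center: bool = False) -> np.ndarray:
    """Similarity matrix X·X'·σβ² induced by a random-effects treatment of X's markers."""
    x_sub = np.atleast_2d(np.asarray(x_sub, dtype=float))
    if center:
        x_sub = center_codes(x_sub)
    return symmetrize(x_sub @ x_sub.T * sigma_beta2)


def build_covariances(
    geno: GenotypeMatrix,
    part: MarkerPartition,
    vc: VarianceComponents,
    center: bool = False,
) -> CovarianceModel:
    """Assemble V2, V12, the similarity matrices and their GRM scalings.

    An empty background set with σβ² > 0 degenerates V2 to I·σe²; this is
    allowed and logged rather than raised, since it is the correct limit.
    """
    x1, x2 = geno.split(part)
    if center:
        x1, x2 = center_codes(x1), center_codes(x2)
    n = geno.n_samples
    p1, p2 = part.p1, part.p2
    p = p1 + p2

    s1 = symmetrize(x1 @ x1.T * vc.sigma_beta2)
    s2 = symmetrize(x2 @ x2.T * vc.sigma_beta2) if p2 else np.zeros((n, n))
    if p2 == 0 and vc.sigma_beta2 > 0:
        logger.info("empty background set: V2 degenerates to I*sigma_e2")

    eye = np.eye(n)
    v2 = symmetrize(s2 + eye * vc.sigma_e2)
    v12 = symmetrize(s1 + s2 + eye * vc.sigma_e2)

    cross_all = (x1 @ x1.T + x2 @ x2.T) if p2 else x1 @ x1.T
    g12 = symmetrize(cross_all / p)
    g2 = symmetrize(x2 @ x2.T / p2) if p2 else np.zeros((n, n))

    return CovarianceModel(
        S2=s2,
        S12=symmetrize(s1 + s2),
        V2=v2,
        V12=v12,
        G2=g2,
        G12=g12,
        sigma_g2_all=p * vc.sigma_beta2,
        sigma_g2_bg=p2 * vc.sigma_beta2,
        vc=vc,
    )


def woodbury_downdate_inverse(
    v12_inv: np.ndarray,
    x1: np.ndarray,
    sigma_beta2: float,
    cond_max: float = 1e12,
) -> np.ndarray:
    """V2⁻¹ from V12⁻¹ by the Sherman–Morrison–Woodbury rank-p1 down-date.

        V2⁻¹ = V12⁻¹ + σβ² V12⁻¹X1 (I − σβ² X1'V12⁻¹X1)⁻¹ X1'V12⁻¹

    Only a p1×p1 system (the capacitance matrix) is solved, so removing the
    tested markers from the covariance costs O(n²p1) given V12⁻¹.

    Raises
    ------
    SingularDowndateError
        If the capacitance matrix I − σβ²X1'V12⁻¹X1 is numerically singular
        (condition number above ``cond_max``).
    """
    v12_inv = np.asarray(v12_inv, dtype=float)
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    if x1.shape[0] != v12_inv.shape[0]:
        raise DimensionError(
            f"X1 has {x1.shape[0]} rows but V12_inv is {v12_inv.shape[0]}x{v12_inv.shape[1]}"
        )
    if sigma_beta2 == 0:
        return v12_inv

    w = v12_inv @ x1                                   # n x p1
    cap = np.eye(x1.shape[1]) - sigma_beta2 * (x1.T @ w)
    # judge singularity against unit scale: cap = I - M should be O(1), so a
    # tiny smallest singular value means the down-dated V2 is near-singular
    sv = np.linalg.svd(cap, compute_uv=False)
    cond = max(sv.max(), 1.0) / max(sv.min(), np.finfo(float).tiny)
    if not np.isfinite(cond) or cond > cond_max:
        raise SingularDowndateError(
            "capacitance matrix I - sigma_beta2*X1'V12^-1*X1 is numerically "
            f"singular (condition number {cond:.3e} > {cond_max:.1e})",
            condition_number=float(cond),
        )
    v2_inv = v12_inv + sigma_beta2 * (w @ np.linalg.solve(cap, w.T))
    return symmetrize(v2_inv)
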