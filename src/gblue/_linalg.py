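"""Shared dense linear-algebra helpers.

Everything here operates on plain ndarrays. Symmetric positive-definite
solves go through Cholesky; explicit inverses are formed only where a
formula reuses the inverse as an object (the all-marker covariance inverse,
reused across every tested set in a scan). On factorization failure a small
diagonal jitter is added once, with a warning, before giving up.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg as sla

from .exceptions import RankDeficiencyError

__all__ = [
    "symmetrize",
    "spd_solve",
    "spd_inverse",
    "assert_full_column_rank",
]


def symmetrize(a: np.ndarray) -> np.ndarray:
    """Return (A + A')/2, suppressing floating-point asymmetry."""
    return (a + a.T) / 2.0


def _cho_with_jitter(a: np.ndarray, jitter: float):
    try:
        return sla.cho_factor(a, lower=True), a
    except np.linalg.LinAlgError:
        if jitter <= 0:
            raise
        warnings.warn(
            f"Cholesky factorization failed; retrying with diagonal jitter {jitter:.3e}",
            RuntimeWarning,
            stacklevel=3,
        )
        a_j = a + jitter * np.eye(a.shape[0])
        return sla.cho_factor(a_j, lower=True), a_j


def spd_solve(a: np.ndarray, b: np.ndarray, jitter: float = 0.0) -> np.ndarray:
    """Solve A x = b for symmetric positive-definite A via Cholesky.

    Parameters
    ----------
    a : (m, m) symmetric positive-definite matrix.
    b : (m,) or (m, k) right-hand side.
    jitter : fallback diagonal perturbation used (once, with a warning) if
        the factorization fails; 0 disables the fallback.
    """
    a = symmetrize(np.asarray(a, dtype=float))
    factor, _ = _cho_with_jitter(a, jitter)
    return sla.cho_solve(factor, np.asarray(b, dtype=float))


def spd_inverse(a: np.ndarray, jitter: float = 0.0) -> np.ndarray:
    """Explicit inverse of a symmetric positive-definite matrix.

    Prefer :func:`spd_solve`; this exists for inverses that are reused as
    objects across many solves.
    """
    a = symmetrize(np.asarray(a, dtype=float))
    inv = spd_solve(a, np.eye(a.shape[0]), jitter=jitter)
    return symmetrize(inv)


def assert_full_column_rank(x: np.ndarray, name: str = "X1", rtol: float = 1e-10) -> None:
    """Raise :class:`RankDeficiencyError` unless ``x`` has full column rank.

    Rank is judged from a column-pivoted QR: columns whose R diagonal falls
    below ``rtol * ||x||`` are reported as dependent. A QR-based pre-check
    gives a clearer failure than a singular downstream solve.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, p = x.shape
    if p == 0:
        raise RankDeficiencyError(f"{name} has no columns")
    if p > n:
        raise RankDeficiencyError(
            f"{name} has more columns ({p}) than rows ({n}); cannot have full column rank",
            dependent_columns=list(range(n, p)),
        )
    _, r, piv = sla.qr(x, mode="economic", pivoting=True)
    scale = np.linalg.norm(x)
    diag = np.abs(np.diag(r))
    bad = diag <= rtol * max(scale, np.finfo(float).tiny)
    if bad.any():
        dep = sorted(int(piv[j]) for j in np.nonzero(bad)[0])
        raise RankDeficiencyError(
            f"{name} is rank deficient: columns {dep} are linearly dependent "
            f"on the others (tolerance {rtol:.1e}·||{name}||)",
            dependent_columns=dep,
        )
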