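"""Core data containers.

The containers are deliberately thin: an n×p genotype-code matrix with
identifiers, a phenotype vector, a tested/background marker partition, and
the two flavours of effect-variance specification — a scalar i.i.d. pair
(σβ², σe²) or full block covariance matrices (B11, B22, B12, R) for
structured marker effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._linalg import symmetrize
from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "MarkerPartition",
    "VarianceComponents",
    "EffectCovariance",
]

# eigenvalue slack, relative to matrix scale, when judging semidefiniteness
_PSD_RTOL = 1e-8


@dataclass
class GenotypeMatrix:
    """n samples × p markers of additive genotype codes.

    Codes are real-valued: raw allele counts {0, 1, 2} as produced by the
    simulator or a PLINK-RAW file, or centered values if the caller chose
    to center. Every identity implemented in this package holds for
    arbitrary real codes.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise DimensionError("genotype codes must be a 2-D array")
        n, p = self.codes.shape
        if len(self.sample_ids) != n:
            raise DimensionError(
                f"{len(self.sample_ids)} sample IDs for {n} genotype rows"
            )
        if len(self.marker_ids) != p:
            raise DimensionError(
                f"{len(self.marker_ids)} marker IDs for {p} genotype columns"
            )
        if not np.all(np.isfinite(self.codes)):
            raise ConfigurationError("genotype codes contain non-finite entries")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def partition(self, tested) -> "MarkerPartition":
        """Partition markers into a tested set and the complementary background.

        ``tested`` may be marker IDs or integer column indices. The
        background is every remaining marker, in original column order —
        the per-test partitioning rule of a scan.
        """
        idx = _as_marker_indices(self, tested)
        mask = np.ones(self.n_markers, dtype=bool)
        mask[idx] = False
        return MarkerPartition(tested=idx, background=np.nonzero(mask)[0])

    def split(self, part: "MarkerPartition") -> tuple[np.ndarray, np.ndarray]:
        """Return (X1, X2) design matrices for a partition."""
        part.validate(self.n_markers)
        return self.codes[:, part.tested], self.codes[:, part.background]


def _as_marker_indices(geno: GenotypeMatrix, tested) -> np.ndarray:
    tested = list(tested)
    if tested and all(isinstance(t, str) for t in tested):
        lookup = {m: j for j, m in enumerate(geno.marker_ids)}
        missing = [t for t in tested if t not in lookup]
        if missing:
            raise ConfigurationError(f"unknown marker IDs: {missing}")
        idx = np.array([lookup[t] for t in tested], dtype=int)
    else:
        idx = np.asarray(tested, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= geno.n_markers):
            raise ConfigurationError("tested marker index out of range")
    if len(set(idx.tolist())) != len(idx):
        raise ConfigurationError("tested marker set contains duplicates")
    return idx


@dataclass
class PhenotypeVector:
    """Phenotype values with sample identifiers."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.sample_ids) != self.values.size:
            raise DimensionError(
                f"{len(self.sample_ids)} sample IDs for {self.values.size} phenotypes"
            )
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("phenotypes contain non-finite values")

    def aligned_to(self, sample_ids: list[str]) -> "PhenotypeVector":
        """Reorder to match ``sample_ids``; raises on any mismatch."""
        from .exceptions import SampleJoinError

        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        extra = [s for s in self.sample_ids if s not in set(sample_ids)]
        if missing or extra:
            raise SampleJoinError(
                f"sample IDs do not match: {len(missing)} genotyped samples lack "
                f"phenotypes {missing[:5]}, {len(extra)} phenotyped samples lack "
                f"genotypes {extra[:5]}",
                offenders=missing + extra,
            )
        order = [pos[s] for s in sample_ids]
        return PhenotypeVector(list(sample_ids), self.values[order])


@dataclass
class MarkerPartition:
    """Ordered tested/background column indices defining X1 and X2."""

    tested: np.ndarray
    background: np.ndarray

    def __post_init__(self):
        self.tested = np.asarray(self.tested, dtype=int)
        self.background = np.asarray(self.background, dtype=int)
        if self.tested.size < 1:
            raise ConfigurationError("tested set must contain at least one marker")
        if set(self.tested.tolist()) & set(self.background.tolist()):
            raise ConfigurationError("tested and background sets overlap")

    @property
    def p1(self) -> int:
        return self.tested.size

    @property
    def p2(self) -> int:
        return self.background.size

    def validate(self, n_markers: int) -> None:
        all_idx = np.concatenate([self.tested, self.background])
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= n_markers):
            raise ConfigurationError("partition index out of range for genotype matrix")


@dataclass
class VarianceComponents:
    """Known scalar variance components (σβ², σe²).

    ``lam`` is the variance ratio σe²/σβ² appearing on the diagonal of the
    mixed-model equations; it is defined only for σβ² > 0.
    """

    sigma_beta2: float
    sigma_e2: float

    def __post_init__(self):
        if self.sigma_beta2 < 0:
            raise ConfigurationError("sigma_beta2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ConfigurationError("sigma_e2 must be > 0")

    @property
    def lam(self) -> float:
        if self.sigma_beta2 == 0:
            raise ConfigurationError(
                "lambda = sigma_e2/sigma_beta2 is undefined for sigma_beta2 = 0"
            )
        return self.sigma_e2 / self.sigma_beta2


@dataclass
class EffectCovariance:
    """Block covariance of marker effects, plus residual covariance.

    The joint effect covariance is [[B11, B12], [B21, B22]] with
    B21 = B12'. R is the residual covariance (default I·σe² supplied by the
    caller). B11 and B22 must be symmetric positive definite and the joint
    matrix positive semidefinite.
    """

    B11: np.ndarray
    B22: np.ndarray
    B12: np.ndarray | None = None
    R: np.ndarray | None = None

    def __post_init__(self):
        self.B11 = symmetrize(np.atleast_2d(np.asarray(self.B11, dtype=float)))
        self.B22 = symmetrize(np.atleast_2d(np.asarray(self.B22, dtype=float)))
        p1, p2 = self.B11.shape[0], self.B22.shape[0]
        if self.B12 is None:
            self.B12 = np.zeros((p1, p2))
        self.B12 = np.atleast_2d(np.asarray(self.B12, dtype=float))
        if self.B12.shape != (p1, p2):
            raise DimensionError(
                f"B12 must be {p1}x{p2}, got {self.B12.shape}"
            )
        if self.R is not None:
            self.R = symmetrize(np.atleast_2d(np.asarray(self.R, dtype=float)))
        for name, block in (("B11", self.B11), ("B22", self.B22)):
            ev = np.linalg.eigvalsh(block)
            if ev.min() <= 0:
                raise ConfigurationError(f"{name} must be positive definite")
        joint = self.joint()
        ev = np.linalg.eigvalsh(joint)
        scale = max(abs(ev).max(), 1.0)
        if ev.min() < -_PSD_RTOL * scale:
            raise ConfigurationError(
                "joint effect covariance [[B11,B12],[B21,B22]] is not positive "
                f"semidefinite (min eigenvalue {ev.min():.3e})"
            )

    @property
    def B21(self) -> np.ndarray:
        return self.B12.T

    @property
    def p1(self) -> int:
        return self.B11.shape[0]

    @property
    def p2(self) -> int:
        return self.B22.shape[0]

    def joint(self) -> np.ndarray:
        return np.block([[self.B11, self.B12], [self.B21, self.B22]])

    @classmethod
    def from_scalars(
        cls,
        p1: int,
        p2: int,
        sigma_beta2: float,
        sigma_e2: float,
        n: int | None = None,
        b12: np.ndarray | None = None,
    ) -> "EffectCovariance":
        """Scalar i.i.d. blocks σβ²·I with optional cross-covariance B12."""
        return cls(
            B11=sigma_beta2 * np.eye(p1),
            B22=sigma_beta2 * np.eye(p2),
            B12=b12,
            R=None if n is None else sigma_e2 * np.eye(n),
        )
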