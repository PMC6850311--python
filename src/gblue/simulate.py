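"""Synthetic genotype/effect/phenotype generator.

Emulates exactly the sampling assumptions of the whole-genome regression
model so that every algebraic identity in the package is testable without
external data: additive genotype codes drawn column-wise as Binomial(2, f)
with allele frequency f uniform on a configured range, i.i.d. N(0, σβ²)
marker effects (or a jointly Gaussian block-correlated pair of effect
vectors), and i.i.d. N(0, σe²) residuals.

Randomness uses one root seed split into independent child streams for
genotypes, effects and residuals (``numpy.random.SeedSequence.spawn``), so
each component can be regenerated on its own.

Deliberately NOT emulated: linkage disequilibrium between loci (columns
are independent), allele-frequency ascertainment, missing genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datatypes import EffectCovariance, GenotypeMatrix, PhenotypeVector
from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_effects",
    "simulate_phenotypes",
    "simulate_dataset",
]

#: bounded retries for redrawing a monomorphic genotype column
MONOMORPHIC_RETRIES = 100

# child-stream order for SeedSequence.spawn
_STREAM_GENOTYPES, _STREAM_EFFECTS, _STREAM_RESIDUALS = 0, 1, 2


@dataclass
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``fixed_alpha`` holds true fixed effects for the first ``len(fixed_alpha)``
    markers (the tested set); ``block_cov`` optionally correlates the tested
    and background effect blocks.
    """

    n_samples: int = 100
    n_markers: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    sigma_beta2: float = 1.0
    sigma_e2: float = 1.0
    fixed_alpha: np.ndarray | None = None
    block_cov: EffectCovariance | None = None
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}"
            )
        if self.n_samples < 2 or self.n_markers < 2:
            raise ConfigurationError("need n_samples >= 2 and n_markers >= 2")
        if self.sigma_beta2 < 0:
            raise ConfigurationError("sigma_beta2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ConfigurationError("sigma_e2 must be > 0")
        if self.fixed_alpha is not None:
            self.fixed_alpha = np.asarray(self.fixed_alpha, dtype=float).ravel()


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[stream])


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an n×p matrix of additive codes in {0, 1, 2}.

    Each column j has its own allele frequency fj ~ Uniform(maf_range) and
    entries Binomial(2, fj). Monomorphic columns are redrawn up to
    :data:`MONOMORPHIC_RETRIES` times, then accepted with a warning (at
    small n and low frequency a constant column is a legitimate draw).
    """
    rng = _child_rng(config.seed, _STREAM_GENOTYPES)
    n, p = config.n_samples, config.n_markers
    lo, hi = config.maf_range
    codes = np.empty((n, p), dtype=float)
    stubborn = []
    for j in range(p):
        for _ in range(MONOMORPHIC_RETRIES + 1):
            f = rng.uniform(lo, hi)
            col = rng.binomial(2, f, size=n).astype(float)
            if col.min() != col.max():
                break
        else:
            stubborn.append(j)
        codes[:, j] = col
    if stubborn:
        warnings.warn(
            f"{len(stubborn)} genotype column(s) remained monomorphic after "
            f"{MONOMORPHIC_RETRIES} redraws: {stubborn[:10]}",
            RuntimeWarning,
            stacklevel=2,
        )
    return GenotypeMatrix(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        marker_ids=[f"m{j:04d}" for j in range(p)],
        codes=codes,
    )


def simulate_effects(
    p1: int,
    p2: int,
    sigma_beta2: float,
    block_cov: EffectCovariance | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw tested/background marker-effect vectors.

    Without ``block_cov`` all p1 + p2 effects are i.i.d. N(0, σβ²). With
    ``block_cov`` the stacked vector is one draw from N(0, [[B11, B12],
    [B21, B22]]); σβ² is then ignored. Semidefinite joint covariances are
    handled by an eigendecomposition square root.
    """
    rng = _child_rng(seed, _STREAM_EFFECTS)
    if block_cov is None:
        if sigma_beta2 < 0:
            raise ConfigurationError("sigma_beta2 must be >= 0")
        effects = rng.standard_normal(p1 + p2) * np.sqrt(sigma_beta2)
        return effects[:p1], effects[p1:]
    if block_cov.p1 != p1 or block_cov.p2 != p2:
        raise ConfigurationError(
            f"block_cov dimensions ({block_cov.p1},{block_cov.p2}) do not match "
            f"(p1,p2)=({p1},{p2})"
        )
    joint = block_cov.joint()
    # PSD square root; EffectCovariance already rejected indefinite joints
    w, v = np.linalg.eigh(joint)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    effects = root @ rng.standard_normal(p1 + p2)
    return effects[:p1], effects[p1:]


def simulate_phenotypes(
    x1: np.ndarray,
    x2: np.ndarray,
    alpha: np.ndarray,
    beta1: np.ndarray,
    beta2: np.ndarray,
    sigma_e2: float,
    seed: int = 0,
) -> PhenotypeVector:
    """y = X1(α + β1) + X2·β2 + e with e i.i.d. N(0, σe²).

    Setting α = 0 and β1 = 0 gives the plain background-only regression;
    nuisance location effects are assumed pre-eliminated, so no intercept
    is added.
    """
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    alpha = np.asarray(alpha, dtype=float).ravel()
    beta1 = np.asarray(beta1, dtype=float).ravel()
    beta2 = np.asarray(beta2, dtype=float).ravel()
    n = x1.shape[0]
    if x2.shape[0] != n:
        raise DimensionError(f"X1 has {n} rows but X2 has {x2.shape[0]}")
    if alpha.size != x1.shape[1] or beta1.size != x1.shape[1]:
        raise DimensionError(
            f"alpha/beta1 lengths ({alpha.size},{beta1.size}) do not match X1 columns "
            f"({x1.shape[1]})"
        )
    if beta2.size != x2.shape[1]:
        raise DimensionError(
            f"beta2 length {beta2.size} does not match X2 columns ({x2.shape[1]})"
        )
    if sigma_e2 <= 0:
        raise ConfigurationError("sigma_e2 must be > 0")
    rng = _child_rng(seed, _STREAM_RESIDUALS)
    e = rng.standard_normal(n) * np.sqrt(sigma_e2)
    y = x1 @ (alpha + beta1) + x2 @ beta2 + e
    return PhenotypeVector(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        values=y,
    )


def simulate_dataset(config: SimulationConfig, p1: int | None = None):
    """Simulate a complete (genotypes, phenotypes, truth) triple.

    The first ``p1`` markers are the tested set; ``p1`` defaults to the
    length of ``config.fixed_alpha`` (or 1). Returns
    ``(GenotypeMatrix, PhenotypeVector, truth_dict)`` with the true effect
    vectors in ``truth_dict``.
    """
    if p1 is None:
        p1 = 1 if config.fixed_alpha is None else config.fixed_alpha.size
    if p1 >= config.n_markers:
        raise ConfigurationError("p1 must be smaller than n_markers")
    geno = simulate_genotypes(config)
    p2 = config.n_markers - p1
    beta1, beta2 = simulate_effects(
        p1, p2, config.sigma_beta2, block_cov=config.block_cov, seed=config.seed
    )
    alpha = (
        np.zeros(p1) if config.fixed_alpha is None else config.fixed_alpha
    )
    if alpha.size != p1:
        raise ConfigurationError(
            f"fixed_alpha has length {alpha.size} but tested set has {p1} markers"
        )
    x1, x2 = geno.codes[:, :p1], geno.codes[:, p1:]
    pheno = simulate_phenotypes(
        x1, x2, alpha, beta1, beta2, config.sigma_e2, seed=config.seed
    )
    pheno.sample_ids = list(geno.sample_ids)
    truth = {"alpha": alpha, "beta1": beta1, "beta2": beta2, "p1": p1}
    return geno, pheno, truth
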