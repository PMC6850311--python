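import numpy as np
import pytest

from gblue.datatypes import VarianceComponents
from gblue.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_instance():
    """A small simulated instance with two tested markers and its partition."""
    cfg = SimulationConfig(
        n_samples=30,
        n_markers=60,
        sigma_beta2=0.5,
        sigma_e2=1.0,
        fixed_alpha=np.array([0.5, -0.3]),
        seed=7,
    )
    geno, pheno, truth = simulate_dataset(cfg, p1=2)
    part = geno.partition([0, 1])
    vc = VarianceComponents(cfg.sigma_beta2, cfg.sigma_e2)
    return geno, pheno, part, vc, truth
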