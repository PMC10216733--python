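import numpy as np
import pytest

from longscca.simulate import (
    SimulationConfig,
    generate_joint_longitudinal,
    generate_multisubspace,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact coupled two-view dataset with strong signal."""
    cfg = SimulationConfig(
        n_samples=60, p_pheno=12, q_gene=20, n_timepoints=3, noise_sigma=1.0, seed=7
    )
    return generate_joint_longitudinal(cfg)


@pytest.fixture(scope="session")
def subspace_view():
    """Three planted 3-D subspaces in 20-D ambient space, light noise."""
    return generate_multisubspace(
        n_per_class=30, ambient_dim=20, subspace_dim=3, n_classes=3,
        noise_sigma=0.05, seed=11,
    )
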