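import numpy as np
import pytest

from mptriage import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A compact planted-class study shared across read-only tests."""
    cfg = SimulationConfig(
        n_genes=600,
        n_planted_per_class=20,
        n_noise_genes=40,
        n_outlier_samples=0,
        rng_seed=11,
    )
    return cfg, *simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """A pure-null study: groups differ only by replicate noise."""
    cfg = SimulationConfig(
        n_genes=400,
        n_planted_per_class=0,
        n_noise_genes=0,
        n_outlier_samples=0,
        rng_seed=5,
    )
    return cfg, *simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
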