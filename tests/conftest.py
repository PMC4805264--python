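import numpy as np
import pytest
from hypothesis import settings

from netretest import SimulationConfig, simulate_dataset

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 3 networks, 3 subjects per group, 40 volumes."""
    return SimulationConfig(
        grid_dims=(12, 12, 12),
        n_networks=3,
        n_subjects_per_group=3,
        n_timepoints=40,
        sigma_between=0.4,
        sigma_within=0.1,
        sigma_noise=1.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def noiseless_config():
    """Exact-recovery regime: no temporal noise."""
    return SimulationConfig(
        grid_dims=(12, 12, 12),
        n_networks=3,
        n_subjects_per_group=2,
        n_timepoints=40,
        sigma_between=0.4,
        sigma_within=0.1,
        sigma_noise=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def noiseless_study(noiseless_config):
    return simulate_dataset(noiseless_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
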