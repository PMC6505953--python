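import numpy as np
import pytest
from hypothesis import settings

from alphactf import SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but fully counterbalanced configuration for fast tests."""
    return SimulationConfig(
        n_subjects=4, n_trials_per_condition=128, n_electrodes=12, seed=0
    )


@pytest.fixture
def noiseless_config():
    """Noise-free, jitter-free configuration: trials sit on bin centers."""
    return SimulationConfig(
        n_subjects=1,
        n_trials_per_condition=64,
        n_electrodes=12,
        noise_sd_one_item=0.0,
        noise_sd_two_item=0.0,
        jitter_width=0.0,
    )
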