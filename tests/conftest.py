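import numpy as np
import pytest

from tremorclust import SimulationConfig, instances_from_config


@pytest.fixture(scope="session")
def noise_free_config() -> SimulationConfig:
    """Tiny noise-free cohort with pinned 5 Hz tremor and separated bands."""
    return SimulationConfig(
        n_per_severity={0: 2, 1: 2, 2: 2, 3: 2},
        amplitude_bands={0: (0.0, 0.0), 1: (2.2, 2.4), 2: (3.3, 3.6), 3: (4.95, 5.4)},
        tremor_freq_range=(5.0, 5.0),
        noise_sd=0.0,
        rest_duration=10.0,
        n_rest_intervals=2,
        filler_duration=5.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def noise_free_instances(noise_free_config):
    return instances_from_config(noise_free_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
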