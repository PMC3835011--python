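import numpy as np
import pytest

from ergflow import CohortConfig, NoiseConfig, TABLE1_PARAMS, generate_cohort


@pytest.fixture(scope="session")
def table1():
    return TABLE1_PARAMS


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Noise-free high-MAP cohort on the full 23-step staircase."""
    config = CohortConfig(noise=NoiseConfig(0.0, 0.0, 0.0), seed=0)
    animals, summary = generate_cohort(config)
    return animals, summary


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default-noise high-MAP cohort (n = 6 animals, seeded)."""
    config = CohortConfig(seed=42)
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
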