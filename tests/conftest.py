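import numpy as np
import pytest

from rsalight.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study design used across tests (12^3 grid, 20 trials)."""
    return SimulationConfig(
        grid_shape=(12, 12, 12),
        n_volumes=250,
        n_words=10,
        n_reps=2,
        n_subjects_per_group=(3, 3),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
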