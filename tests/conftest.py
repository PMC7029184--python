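import numpy as np
import pytest

from paramwm import pipeline, stimgen, synthetic_bold


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def example_run():
    return stimgen.make_run(0, 2024)


@pytest.fixture(scope="session")
def small_config():
    """A fast simulation geometry used by unit/integration tests."""
    return synthetic_bold.SimConfig(
        grid_shape=(16, 16, 15),
        n_volumes_per_run=80,
        n_runs=4,
        n_subjects=1,
        snr=2.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_subject(small_config):
    return synthetic_bold.simulate_subject(small_config, 0)


@pytest.fixture(scope="session")
def small_betamaps(small_subject):
    return pipeline.subject_betamaps(small_subject)
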