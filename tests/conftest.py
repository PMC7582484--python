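import numpy as np
import pytest

from gaitq import GaitModelParams, generate_walking_accel


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless compass-gait parameters with an integer-sample stride
    (step 2.0 Hz at 100 Hz -> stride period exactly 100 samples)."""
    return GaitModelParams(
        step_frequency=2.0,
        phase_jitter_sd=0.0,
        amplitude_jitter_sd=0.0,
        sensor_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def clean_walk(clean_params):
    """60 s of noiseless walking."""
    return generate_walking_accel(clean_params, 60.0, seed=1)


@pytest.fixture(scope="session")
def default_walk():
    """60 s of walking at the default (noisy) parameters."""
    return generate_walking_accel(GaitModelParams(), 60.0, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
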