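import numpy as np
import pytest

from gaitslope import GaitScenario, simulate_recording

SLOPES = (0.14, 0.10, 0.06, 0.02, -0.02, -0.05, -0.09)


def noiseless_scenario(**kw) -> GaitScenario:
    kw.setdefault("accel_noise_sd", 0.0)
    kw.setdefault("gyro_noise_sd", 0.0)
    return GaitScenario(**kw)


@pytest.fixture(scope="session")
def noiseless_walk():
    """A clean 30-stride walk on a 6 % grade with its ground truth."""
    scn = noiseless_scenario(slope=0.06, n_strides=30)
    return (scn, *simulate_recording(scn))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
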