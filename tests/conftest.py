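import numpy as np
import pytest

from canopyspace.synth import SimConfig, simulate_batch


@pytest.fixture(scope="session")
def noiseless_cfg() -> SimConfig:
    return SimConfig(seed=11, depth_noise_sd_mm=0.0, rgb_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_batch(noiseless_cfg):
    """One full noiseless batch shared by the geometric tests."""
    return simulate_batch(noiseless_cfg)


@pytest.fixture(scope="session")
def noisy_batch():
    """Default study conditions: 2 mm depth noise, 20 g weight noise."""
    return simulate_batch(SimConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
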