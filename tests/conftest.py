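import numpy as np
import pytest

from wntnoise import NoiseParams, SimConfig


@pytest.fixture
def noiseless_config() -> SimConfig:
    return SimConfig(noise_model="none", unfit_rate=0.0, spike_rate=0.0, seed=0)


@pytest.fixture
def default_params() -> NoiseParams:
    return NoiseParams()


@pytest.fixture
def flat_frame() -> np.ndarray:
    return np.full((20, 20), 100.0)
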