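import numpy as np
import pytest

from cyeff import EffortParams, SamplingConfig


@pytest.fixture
def flat_img():
    return np.full((300, 300), 128.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def random_int_img(rng):
    """An integer-valued 120x120 image (integers are exact in float64)."""
    return rng.integers(0, 256, size=(120, 120)).astype(np.float64)


@pytest.fixture
def default_params():
    return EffortParams()


@pytest.fixture
def small_cfg():
    return SamplingConfig(n_trajectories=25, seed=11)
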