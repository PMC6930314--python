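import numpy as np
import pytest

from seraman import InstrumentSpec, SerumModel


@pytest.fixture
def instrument():
    return InstrumentSpec()


@pytest.fixture
def quiet_instrument():
    """Low-noise instrument with no cosmic rays, for clean-template checks."""
    return InstrumentSpec(noise_sd=0.001, cosmic_ray_rate=0.0)


@pytest.fixture
def serum_model():
    return SerumModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
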