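import numpy as np
import pytest

from avol.network import AreaParams, build_area


@pytest.fixture
def decoupled_params():
    """An area with all coupling off: pure leaky integrators."""
    return AreaParams(noise_sd=0.0, w_ee=0.0, w_ei_ff=0.0, w_ei_fb=0.0,
                      w_ie_ff=0.0, w_ie_fb=0.0, weight_jitter=0.0,
                      tonic_drive=0.0)


@pytest.fixture
def default_area():
    return build_area(AreaParams(), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
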