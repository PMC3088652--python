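import numpy as np
import pytest
from hypothesis import settings

from spikethresh import MembraneParams, NaChannelParams, ThresholdModel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def channel():
    """Default working point: V_T=-55, V_i=-63, k_a=k_i=6 mV."""
    return NaChannelParams(V_T=-55.0, V_i=-63.0, k_a=6.0, k_i=6.0, tau_i=5.0)


@pytest.fixture(scope="session")
def model_exact(channel):
    return ThresholdModel(channel=channel, tau_theta=5.0)


@pytest.fixture(scope="session")
def model_piecewise(channel):
    return ThresholdModel(channel=channel, tau_theta=5.0,
                          steady_state_mode="piecewise")


@pytest.fixture(scope="session")
def membrane():
    return MembraneParams(E_L=-70.0, tau_m=5.0, R=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
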