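import numpy as np
import pytest

from affective_dis import meanfield as mf
from affective_dis import network as nw


@pytest.fixture(scope="session")
def scale_free_60() -> nw.NetworkModel:
    """The small scale-free substrate used by the collective scenarios."""
    return nw.generate_scale_free(60, 2.3, 2, seed=1)


@pytest.fixture(scope="session")
def star_10() -> nw.NetworkModel:
    return nw.star_graph(10)


@pytest.fixture(scope="session")
def ring_6() -> nw.NetworkModel:
    return nw.ring_graph(6)


@pytest.fixture
def single_agent_free() -> mf.AgentParams:
    """One uncoupled, undamped, unpumped agent at resonance (g/kappa = 0.5)."""
    return mf.AgentParams(n=1, Delta=0.0, Gamma=0.0, gamma_plus=0.0,
                          sigma_z0=0.0, g=0.5)


@pytest.fixture
def pumped_agent() -> mf.AgentParams:
    """Agent above the critical arousal: Gamma=0.1, gamma_+=0.5, sz0=0.99."""
    return mf.AgentParams(n=1, Delta=0.5, Gamma=0.1, gamma_plus=0.5,
                          sigma_z0=0.99, g=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
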