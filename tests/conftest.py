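import numpy as np
import pytest

from ifnet.params import BiasConfig, PlasticityParams, SimulationParams
from ifnet.topology import TopologySpec, build_network


@pytest.fixture(scope="session")
def sim():
    return SimulationParams()


@pytest.fixture(scope="session")
def plast():
    return PlasticityParams()


@pytest.fixture(scope="session")
def bias():
    return BiasConfig()


@pytest.fixture(scope="session")
def network(sim, plast):
    return build_network(TopologySpec(), sim, plast, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
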