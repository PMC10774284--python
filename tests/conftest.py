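import numpy as np
import pytest

from biosos.fixtures import toy_cell_network, toy_chain_network, toy_decay_network
from biosos.smn import FluxModel, default_network


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def flux_model(network):
    return FluxModel(network)


@pytest.fixture(scope="session")
def ext_ids(network):
    return [network.metabolite_ids[i] for i in network.ext_index]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_decay():
    net = toy_decay_network()
    return net, FluxModel(net)


@pytest.fixture(scope="session")
def toy_chain():
    net = toy_chain_network()
    return net, FluxModel(net)


@pytest.fixture(scope="session")
def toy_cell():
    net = toy_cell_network()
    return net, FluxModel(net)
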