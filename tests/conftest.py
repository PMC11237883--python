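import numpy as np
import pytest

from dcmrel.constants import ModelConstants
from dcmrel.forward import ModelContext
from dcmrel.network import default_network
from dcmrel.priors import PriorTable


@pytest.fixture(scope="session")
def priors():
    return PriorTable()


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def net1():
    return default_network(1)


@pytest.fixture(scope="session")
def net2():
    return default_network(2)


@pytest.fixture(scope="session")
def net4():
    return default_network(4)


@pytest.fixture(scope="session")
def ctx2(net2, priors, constants):
    return ModelContext(net2, priors, constants)


@pytest.fixture(scope="session")
def ctx1(net1, priors, constants):
    return ModelContext(net1, priors, constants)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def prior_sd_vector(priors, index):
    return np.array([priors.variances[f] for f in index.families]) ** 0.5
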