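import numpy as np
import pytest

import tdss
from tdss.optimizer import TDEConfig


@pytest.fixture(scope="session")
def conf1():
    return tdss.network_5gene("conf1")


@pytest.fixture(scope="session")
def conf2():
    return tdss.network_5gene("conf2")


@pytest.fixture(scope="session")
def conf1_data(conf1):
    """Small noise-free dataset from the 5-gene no-delay network."""
    return tdss.generate_data(conf1, M=2, T=15, seed=1)


@pytest.fixture(scope="session")
def quick_config():
    """A deliberately tiny search budget for smoke tests."""
    return TDEConfig(pop_size=12, phase1_generations=20, mra_generations=5, n_e=5, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
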