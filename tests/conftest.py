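import numpy as np
import pytest

from dualnet.network import NetworkConfig, build_dual_network


@pytest.fixture(scope="session")
def small_config():
    return NetworkConfig(N_E=300, N_I=60, beta=0.4, seed=7)


@pytest.fixture(scope="session")
def small_table(small_config):
    return build_dual_network(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
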