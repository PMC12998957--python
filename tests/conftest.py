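import numpy as np
import pytest

from einet import LIFParams, NetworkParams, SynapticKernel


@pytest.fixture
def lif():
    return LIFParams()


@pytest.fixture
def params():
    return NetworkParams()


@pytest.fixture
def kernel_E():
    return SynapticKernel.excitatory_current()


@pytest.fixture
def kernel_I():
    return SynapticKernel.inhibitory_current()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
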