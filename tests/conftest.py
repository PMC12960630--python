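import numpy as np
import pytest

from spikeql import preset


@pytest.fixture(params=[2, 3, 4, 5], ids=lambda b: f"{b}bit")
def config(request):
    """One reference configuration per counter bit-width."""
    return preset(request.param)


@pytest.fixture
def config3():
    """The 3-bit reference configuration (published parameter set)."""
    return preset(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
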