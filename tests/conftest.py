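import numpy as np
import pytest

from ringpgg import ModelParams


@pytest.fixture
def params():
    """Reference parameters: (N,n)=(100,4), (b,c,f,s)=(2,1,6,3), mu=0.01."""
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_population(params, rng):
    return rng.integers(0, 4, size=params.N).astype(np.int8)
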