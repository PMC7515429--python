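import numpy as np
import pytest

from rldamp import fixtures as fx


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def phantom64():
    return fx.make_phantom(64)


@pytest.fixture
def texture64():
    return fx.make_selfsimilar_image(64, 6, jitter=4.0, seed=1)
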