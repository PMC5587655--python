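import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng):
    """Random positive 8x8 slice."""
    return rng.uniform(0.5, 2.0, size=(8, 8))
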