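import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_image(rng):
    """One 16x16 random uint8 image."""
    return rng.integers(0, 256, (16, 16), dtype=np.uint8)
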