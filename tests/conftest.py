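import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb_images(rng):
    """Ten random 32x32 uint8 RGB images for oracle-equivalence checks."""
    return [rng.integers(0, 256, size=(32, 32, 3), dtype=np.uint8) for _ in range(10)]
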