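import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from glioscan.imaging_io import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """A 32x32 8-bit image quantized to 8 gray levels."""
    return GrayImage((rng.integers(0, 8, size=(32, 32)) * 32).astype(np.uint8))
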