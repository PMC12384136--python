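import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def gaussian_10x2(rng):
    """A fixed seeded 10x2 Gaussian ratings draw."""
    return np.random.default_rng(42).standard_normal((10, 2))
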