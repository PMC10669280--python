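import sys
from pathlib import Path

import numpy as np
import pytest

# make the oracle helpers importable regardless of invocation directory
sys.path.insert(0, str(Path(__file__).parent))


@pytest.fixture
def rng():
    return np.random.default_rng(20230926)


@pytest.fixture
def random_masks():
    """200 fixed-seed random binary masks, up to 8x8."""
    g = np.random.default_rng(4242)
    masks = []
    for _ in range(200):
        h, w = g.integers(3, 9, size=2)
        masks.append(g.random((h, w)) < g.uniform(0.2, 0.7))
    return masks
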