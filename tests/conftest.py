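import numpy as np
import pytest

from segqc.phantoms import GlottisPhantomSpec, make_pair


@pytest.fixture(scope="session")
def phantom_pairs():
    """60 deterministic glottis phantoms shared across the suite."""
    rng = np.random.default_rng(0)
    spec = GlottisPhantomSpec()
    return [make_pair(spec, rng, source_id=f"p{i:03d}") for i in range(60)]


@pytest.fixture(scope="session")
def square_mask():
    m = np.zeros((20, 20), dtype=np.uint8)
    m[5:15, 5:15] = 1
    return m
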