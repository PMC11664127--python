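import numpy as np
import pytest

from bcehi import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A 3 x 300 pixel synthetic world shared across read-only tests."""
    return generate_world(WorldConfig(n_pixels_per_ecotone=300, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
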