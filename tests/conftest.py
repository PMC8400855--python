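import numpy as np
import pytest

import dermcad as dc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scenes():
    """Eight 64x64 scenes shared across pipeline tests."""
    return dc.generate_scenes(8, 0.5, seed=42, canvas_side=64)


@pytest.fixture(scope="session")
def tiny_segnet_cfg():
    """A small valid-mode segmentation config for fast forward passes."""
    return dc.SegNetConfig(base_features=4)
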