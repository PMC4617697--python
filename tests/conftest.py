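import numpy as np
import pytest

from nsctfuse import FusionConfig, fuse_images, make_phantom_pair


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pair():
    """128x128 complementary phantom pair with exclusive-feature masks."""
    return make_phantom_pair(128, seed=7)


@pytest.fixture(scope="session")
def default_cfg():
    return FusionConfig()


@pytest.fixture(scope="session")
def fused_phantom(phantom_pair, default_cfg):
    """One shared end-to-end fusion of the phantom pair (expensive)."""
    return fuse_images(phantom_pair.a, phantom_pair.b, default_cfg)
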