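import numpy as np
import pytest

from lusseg.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240311)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Smallest config exercising every architectural element (64x64, 2 blocks)."""
    return ModelConfig(image_size=64, patch_size=16, embed_dim=64, depth=2,
                       num_heads=2, decoder_channels=[32, 16, 8, 8], seed=7)


def random_mask(rng, shape, p=0.3):
    return (rng.random(shape) < p).astype(np.uint8)
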