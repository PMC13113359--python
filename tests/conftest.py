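import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from retscreen.encoder import EncoderConfig, init_encoder_params
from retscreen.preprocessing import PatchGrid
from retscreen.synthetic import SyntheticConfig, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_grid():
    """3x3 patch grid (12x12 image, 4 px patches)."""
    return PatchGrid(target_size=12, patch_size=4)


@pytest.fixture
def tiny_config(tiny_grid):
    return EncoderConfig(patch_grid=tiny_grid, n_layers=2, embed_dim=8,
                         n_heads=2, fusion_depths=(1, 2))


@pytest.fixture
def tiny_params(tiny_config):
    params = init_encoder_params(tiny_config, seed=7)
    # scale projections up so activations are non-trivial in oracle checks
    return {k: v * 10 if v.ndim >= 2 else v for k, v in params.items()}


@pytest.fixture
def synth_config():
    return SyntheticConfig(image_size=64, seed=99)


@pytest.fixture
def sample(synth_config):
    return generate_sample(synth_config, np.random.default_rng(5))
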