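import numpy as np
import pytest

from chromaharmony import colorspace, synthetic

#: Eight well-separated RGB block colors with the block-mosaic proportions
#: used throughout the palette tests.
BLOCK_COLORS = [
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (1.0, 1.0, 0.0),
    (1.0, 0.0, 1.0),
    (0.0, 1.0, 1.0),
    (1.0, 1.0, 1.0),
    (0.0, 0.0, 0.0),
]
BLOCK_PROPORTIONS = [0.30, 0.20, 0.15, 0.10, 0.10, 0.05, 0.05, 0.05]


@pytest.fixture
def block_fixture():
    return synthetic.make_blocks(BLOCK_COLORS, BLOCK_PROPORTIONS, height=40, width=20)


@pytest.fixture
def gray_ramp_lab():
    ramp = np.linspace(0.0, 1.0, 32)
    rgb = np.broadcast_to(ramp[None, :, None], (4, 32, 3)).copy()
    return colorspace.rgb_to_lab(rgb)


def random_rgb(seed: int, h: int = 8, w: int = 8) -> np.ndarray:
    return np.random.default_rng(seed).random((h, w, 3))
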