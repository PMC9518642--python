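"""Synthetic fixtures with analytically known ground truth.

Every generator is deterministic given its seed and returns the truth
alongside the data (palette, label map, true scores), so downstream tests
never re-derive the expected answer from the generated input itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from chromaharmony import colorspace, palette as palette_mod
from chromaharmony.harmony_model import HarmonyModel


def _as_rgb_color(color) -> np.ndarray:
    c = np.asarray(color, dtype=np.float64)
    if c.shape != (3,):
        raise ValueError(f"color must be an RGB triple, got shape {c.shape}")
    if c.min() < 0 or c.max() > 1:
        raise ValueError("RGB channels must lie in [0, 1]")
    return c


def make_uniform(color, height: int, width: int) -> np.ndarray:
    """Constant RGB image."""
    if height < 1 or width < 1:
        raise ValueError("image must be at least 1x1")
    return np.broadcast_to(_as_rgb_color(color), (height, width, 3)).copy()


def make_two_tone(color_a, color_b, height: int, width: int, split: float = 0.5) -> np.ndarray:
    """Two vertical bands: ``color_a`` on the left ``split`` fraction."""
    img = make_uniform(color_a, height, width)
    cut = int(round(width * split))
    img[:, cut:] = _as_rgb_color(color_b)
    return img


def make_gradient(height: int, width: int, lo: float = 0.0, hi: float = 1.0) -> np.ndarray:
    """Horizontal gray ramp from ``lo`` to ``hi``."""
    ramp = np.linspace(lo, hi, width)
    return np.broadcast_to(ramp[None, :, None], (height, width, 3)).copy()


def make_noise(height: int, width: int, seed: int = 0) -> np.ndarray:
    """Uniform random RGB noise."""
    rng = np.random.default_rng(seed)
    return rng.random((height, width, 3))


@dataclass(frozen=True)
class BlockFixture:
    """A banded mosaic plus the palette and region structure it realizes."""

    image: np.ndarray
    palette: palette_mod.Palette
    labels: np.ndarray


def make_blocks(colors, proportions, height: int, width: int) -> BlockFixture:
    """Horizontal bands with areas proportional to ``proportions``.

    Band heights are apportioned by largest-remainder rounding over rows, so
    the returned ground-truth palette counts match the realized image exactly.
    """
    colors = [_as_rgb_color(c) for c in colors]
    props = np.asarray(proportions, dtype=np.float64)
    if len(colors) != len(props):
        raise ValueError("colors and proportions must have equal length")
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must be non-negative and sum to 1")
    if len(colors) > height:
        raise ValueError(f"cannot fit {len(colors)} bands into {height} rows")
    rows = palette_mod.largest_remainder_widths(props, height)
    if np.any(rows == 0):
        raise ValueError("a band received zero rows; increase the image height")

    img = np.empty((height, width, 3))
    labels = np.empty((height, width), dtype=np.int64)
    r = 0
    for idx, (color, nrows) in enumerate(zip(colors, rows)):
        img[r : r + nrows] = color
        labels[r : r + nrows] = idx + 1
        r += nrows

    lab_colors = colorspace.rgb_to_lab(np.array(colors))
    counts = rows * width
    order = np.lexsort((lab_colors[:, 2], lab_colors[:, 1], lab_colors[:, 0], -counts))
    truth = palette_mod.Palette(lab_colors[order], counts[order])
    return BlockFixture(image=img, palette=truth, labels=labels)


def make_rating_matrix(
    n_materials: int,
    n_raters: int,
    true_scores,
    noise_sd: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Materials × raters grid: true score + Gaussian noise, rounded and
    clipped to the 5-level scale {-2..2}."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    truth = np.asarray(true_scores, dtype=np.float64)
    if truth.shape != (n_materials,):
        raise ValueError(f"true_scores must have shape ({n_materials},)")
    rng = np.random.default_rng(seed)
    raw = truth[:, None] + rng.normal(0.0, noise_sd, size=(n_materials, n_raters))
    scores = np.clip(np.rint(raw), -2, 2).astype(np.int64)
    return pd.DataFrame(
        scores,
        index=[f"material_{i:03d}" for i in range(n_materials)],
        columns=[f"rater_{i:03d}" for i in range(n_raters)],
    )


def make_feature_dataset(
    n: int,
    model: HarmonyModel,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Features uniform on [0, 1] with targets = model prediction + noise."""
    if n < 10:
        raise ValueError("need at least 10 samples")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    names = list(model.feature_names)
    X = pd.DataFrame(rng.random((n, len(names))), columns=names)
    y = np.asarray(model.predict(X), dtype=np.float64)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return X, y
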