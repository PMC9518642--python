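"""Circular mean filtering and grayscale derivation.

The smoothing step suppresses edge/semantic structure before feature
extraction: every channel value is replaced by the mean over a circular
template of radius ``n`` centred on the pixel.  At the borders the template is
intersected with the image support and the mean renormalized — no padding, so
no out-of-image colors are invented.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

#: BT.709 luma weights for grayscale derivation.
LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

DEFAULT_SMOOTH_RADIUS = 50


def disk_template(radius: int) -> np.ndarray:
    """Boolean circular template: offsets with ``dx**2 + dy**2 <= radius**2``."""
    if radius < 0 or int(radius) != radius:
        raise ValueError(f"radius must be a non-negative integer, got {radius!r}")
    radius = int(radius)
    ax = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    return (dx * dx + dy * dy) <= radius * radius


def circular_mean_filter(channel, radius: int) -> np.ndarray:
    """Mean-filter a single 2-D raster with a circular template.

    Border means use only in-image pixels (template intersected with the image
    and the mean renormalized).  The center pixel is included in the template.
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D channel raster, got shape {arr.shape}")
    h, w = arr.shape
    if radius > min(h, w):
        raise ValueError(
            f"smoothing radius {radius} exceeds the smallest image dimension "
            f"{min(h, w)}; choose a radius no larger than min(height, width)"
        )
    template = disk_template(radius).astype(np.float64)
    if template.size == 1:
        return arr.copy()
    num = signal.convolve(arr, template, mode="same", method="auto")
    den = signal.convolve(np.ones_like(arr), template, mode="same", method="auto")
    out = num / den
    # FFT round-off may nudge values outside the input range by ~1e-13.
    return np.clip(out, arr.min(), arr.max())


def smooth_material(img, radius: int = DEFAULT_SMOOTH_RADIUS) -> np.ndarray:
    """Circular mean filter applied independently to the R, G, B channels."""
    rgb = np.asarray(img, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {rgb.shape}")
    return np.stack(
        [circular_mean_filter(rgb[..., c], radius) for c in range(3)], axis=-1
    )


def to_gray(img) -> np.ndarray:
    """BT.709 luma scaled to integers in ``[0, 255]``, rounded half-up."""
    rgb = np.asarray(img, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB raster, got shape {rgb.shape}")
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        raise ValueError("RGB channels must lie in [0, 1]")
    luma = rgb @ LUMA_WEIGHTS
    gray = np.floor(luma * 255.0 + 0.5).astype(np.int64)
    return np.clip(gray, 0, 255)
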