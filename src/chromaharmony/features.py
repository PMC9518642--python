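"""Extraction of the 16-dimensional multi-color physical feature vector.

The vector collects, in fixed order:

====  =============================================================
f1-3  first-order moments (means) of L*, a*, b*
f4-6  second-order moments (population standard deviations)
f7-9  third-order moments (signed cube roots of mean cubed deviations)
f10   color richness: Shannon entropy of the 256-bin grayscale histogram
f11   region count of the watershed segmentation
f12   population standard deviation of watershed region sizes
f13   color-tone contrast: RMS chromatic deviation in the (a*, b*) plane
f14   lightness contrast: mean squared L* difference over 8-neighbor pairs
f15   cool/warm contrast: same neighborhood statistic on the warm-cool raster
f16   area difference: population standard deviation of palette counts
====  =============================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np

from chromaharmony import colorspace, palette as palette_mod, preprocess, segmentation

logger = logging.getLogger(__name__)

FEATURE_NAMES = tuple(f"f{i}" for i in range(1, 17))

# Warm-cool degree constants (color-emotion scale; chroma/hue driven).
WC_OFFSET = -0.89
WC_CHROMA_GAIN = 0.052
WC_HUE_PHASE_DEG = 50.0
WC_SECOND_HARMONIC = 0.16
WC_SECOND_PHASE_DEG = 350.0


@dataclass(frozen=True)
class FeatureVector:
    f1: float
    f2: float
    f3: float
    f4: float
    f5: float
    f6: float
    f7: float
    f8: float
    f9: float
    f10: float
    f11: int
    f12: float
    f13: float
    f14: float
    f15: float
    f16: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=np.float64)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _flat_lab(lab) -> np.ndarray:
    arr = np.asarray(lab, dtype=np.float64)
    if arr.shape[-1] != 3 or arr.size == 0:
        raise ValueError(f"expected a non-empty (..., 3) CIELAB raster, got shape {arr.shape}")
    return arr.reshape(-1, 3)


def signed_cbrt(x):
    """Odd cube root: ``sign(x) * |x|**(1/3)`` (handles negative moments)."""
    return np.cbrt(x)


def color_moments(lab) -> np.ndarray:
    """First, second and third color moments of L*, a*, b* → (f1..f9).

    Means, population standard deviations, and signed cube roots of the mean
    cubed deviations, one triple per channel.
    """
    px = _flat_lab(lab)
    mean = px.mean(axis=0)
    centered = px - mean
    second = np.sqrt((centered**2).mean(axis=0))
    third = signed_cbrt((centered**3).mean(axis=0))
    return np.concatenate([mean, second, third])


def color_richness(gray) -> float:
    """Shannon entropy (bits) of the 256-bin grayscale histogram (f10)."""
    arr = np.asarray(gray)
    if arr.size == 0:
        raise ValueError("empty grayscale raster")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=256)
    p = counts[counts > 0] / arr.size
    return float(-(p * np.log2(p)).sum())


def space_density(labels) -> tuple[int, float]:
    """Region count and population std of region sizes → (f11, f12)."""
    sizes = segmentation.region_sizes(labels)
    return int(sizes.size), float(sizes.std())


def color_tone_contrast(lab) -> float:
    """Root mean squared chromatic deviation from the mean (a*, b*) point (f13)."""
    px = _flat_lab(lab)
    ab = px[:, 1:]
    centered = ab - ab.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def neighbor_mean_sq_diff(raster, connectivity: int = 8) -> float:
    """Mean squared difference over all ordered in-image neighbor pairs.

    Every pixel is compared with each of its in-image neighbors; the squared
    differences are summed and divided by the number of (center, neighbor)
    ordered pairs.  Border pixels contribute only their in-image neighbors
    (no padding).  A single-pixel raster has no pairs and returns 0.
    """
    arr = np.asarray(raster, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D raster, got shape {arr.shape}")
    h, w = arr.shape
    total = 0.0
    pairs = 0
    for dr, dc in segmentation._offsets(connectivity):
        rs_a = slice(max(dr, 0), h + min(dr, 0))
        cs_a = slice(max(dc, 0), w + min(dc, 0))
        rs_b = slice(max(-dr, 0), h + min(-dr, 0))
        cs_b = slice(max(-dc, 0), w + min(-dc, 0))
        diff = arr[rs_a, cs_a] - arr[rs_b, cs_b]
        total += float((diff * diff).sum())
        pairs += diff.size
    if pairs == 0:
        logger.warning("neighbor contrast on a single-pixel raster: no pairs, returning 0")
        return 0.0
    return total / pairs


def lightness_contrast(lab) -> float:
    """Mean squared L* difference over 8-neighbor pairs (f14, squared-L* units)."""
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) CIELAB raster, got shape {arr.shape}")
    return neighbor_mean_sq_diff(arr[..., 0])


def coolwarm_degree(hue_chroma) -> np.ndarray:
    """Per-pixel warm-cool degree from hue angle (degrees) and chroma.

    ``WC = -0.89 + 0.052 C* [cos(h - 50°) + 0.16 cos(2h - 350°)]``;
    achromatic pixels (C* = 0) sit at the constant -0.89.
    """
    hc = np.asarray(hue_chroma, dtype=np.float64)
    if hc.shape[-1] != 2:
        raise ValueError(f"expected (..., 2) hue/chroma input, got shape {hc.shape}")
    h_rad = np.radians(hc[..., 0])
    chroma = hc[..., 1]
    modulation = np.cos(h_rad - np.radians(WC_HUE_PHASE_DEG)) + WC_SECOND_HARMONIC * np.cos(
        2.0 * h_rad - np.radians(WC_SECOND_PHASE_DEG)
    )
    return WC_OFFSET + WC_CHROMA_GAIN * chroma * modulation


def coolwarm_contrast(wc_raster) -> float:
    """Mean squared warm-cool difference over 8-neighbor pairs (f15)."""
    return neighbor_mean_sq_diff(np.asarray(wc_raster, dtype=np.float64))


def area_difference(p: palette_mod.Palette) -> float:
    """Population standard deviation of the palette pixel counts (f16)."""
    return float(np.asarray(p.counts, dtype=np.float64).std())


def extract_all(
    img,
    *,
    smooth_radius: int = preprocess.DEFAULT_SMOOTH_RADIUS,
    palette_j: int = palette_mod.DEFAULT_CLUSTERS,
    palette_seed: int = 0,
    connectivity: int = 8,
    gamma: bool = False,
) -> FeatureVector:
    """Run the full pipeline on an RGB raster and return f1..f16.

    Pipeline order: circular smoothing → CIELAB conversion (plus grayscale,
    hue/chroma, palette, watershed of the smoothed image) → features.
    """
    rgb = np.asarray(img, dtype=np.float64)
    smoothed = preprocess.smooth_material(rgb, radius=smooth_radius)
    lab = colorspace.rgb_to_lab(smoothed, gamma=gamma)
    gray = preprocess.to_gray(smoothed)
    labels = segmentation.watershed_immersion(gray, connectivity=connectivity)
    hc = colorspace.lab_to_hue_chroma(lab)
    pal = palette_mod.kmeans_palette(lab, j=palette_j, seed=palette_seed)

    moments = color_moments(lab)
    f10 = color_richness(gray)
    f11, f12 = space_density(labels)
    f13 = color_tone_contrast(lab)
    f14 = lightness_contrast(lab)
    f15 = coolwarm_contrast(coolwarm_degree(hc))
    f16 = area_difference(pal)

    return FeatureVector(
        *[float(m) for m in moments], f10, f11, f12, f13, f14, f15, f16
    )
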