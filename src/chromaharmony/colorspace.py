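"""RGB → XYZ → CIELAB conversion chain and hue-angle/chroma derivation.

All rasters are ``float64`` numpy arrays of shape ``(H, W, 3)`` (or ``(..., 3)``
for single colors), row-major, origin at the top-left, 0-based ``(row, column)``
coordinates.  RGB channels live in ``[0, 1]``; 8-bit input is divided by 255.

The forward chain applies the BT.709 primaries matrix directly to the
normalized R, G, B values — no sRGB gamma expansion by default.  An optional
``gamma`` flag enables standard sRGB decoding for users who want the
colorimetrically conventional chain.
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

#: BT.709 RGB → XYZ matrix (D65).
RGB_TO_XYZ_MATRIX = np.array(
    [
        [0.412453, 0.357580, 0.180423],
        [0.212671, 0.715160, 0.072169],
        [0.019334, 0.119193, 0.950227],
    ]
)

#: D65 reference white in XYZ (the row sums of :data:`RGB_TO_XYZ_MATRIX`).
D65_WHITE = np.array([0.950456, 1.0, 1.088754])

# Knot of the piecewise CIELAB transfer function.
_EPSILON = (6.0 / 29.0) ** 3
_LINEAR_SLOPE = (29.0 / 6.0) ** 2 / 3.0
_LINEAR_OFFSET = 16.0 / 116.0


def _as_color_array(arr, name: str = "image") -> np.ndarray:
    out = np.asarray(arr, dtype=np.float64)
    if out.ndim < 1 or out.shape[-1] != 3:
        raise ValueError(f"{name} must have 3 channels in the last axis, got shape {out.shape}")
    if not np.all(np.isfinite(out)):
        raise ValueError(f"{name} contains non-finite values")
    return out


def decode_uint8(img) -> np.ndarray:
    """Map an 8-bit-per-channel raster to float channels in ``[0, 1]``."""
    return np.asarray(img, dtype=np.float64) / 255.0


def srgb_gamma_expand(rgb: np.ndarray) -> np.ndarray:
    """Standard sRGB electro-optical decoding (only used when ``gamma=True``)."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return np.where(rgb <= 0.04045, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)


def srgb_gamma_compress(rgb: np.ndarray) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=np.float64)
    return np.where(rgb <= 0.0031308, rgb * 12.92, 1.055 * np.maximum(rgb, 0.0) ** (1 / 2.4) - 0.055)


def rgb_to_xyz(img, *, gamma: bool = False) -> np.ndarray:
    """Convert normalized RGB to XYZ by the BT.709 linear matrix.

    Parameters
    ----------
    img
        ``(..., 3)`` array with channels in ``[0, 1]``.
    gamma
        If True, apply sRGB gamma expansion before the matrix (default off:
        the matrix is applied to the raw normalized channels).
    """
    rgb = _as_color_array(img, "rgb image")
    if rgb.min() < 0.0 or rgb.max() > 1.0:
        raise ValueError(
            f"RGB channels must lie in [0, 1]; got range [{rgb.min():g}, {rgb.max():g}]"
        )
    if gamma:
        rgb = srgb_gamma_expand(rgb)
    return rgb @ RGB_TO_XYZ_MATRIX.T


def normalize_d65(xyz) -> np.ndarray:
    """Divide XYZ by the D65 white point, mapping white to ``(1, 1, 1)``."""
    return _as_color_array(xyz, "xyz") / D65_WHITE


def lab_transfer(t):
    """Piecewise cube-root transfer: ``t**(1/3)`` above the knot, linear below."""
    t = np.asarray(t, dtype=np.float64)
    cube_root = np.cbrt(np.where(t > _EPSILON, t, 1.0))
    linear = _LINEAR_SLOPE * t + _LINEAR_OFFSET
    out = np.where(t > _EPSILON, cube_root, linear)
    return out if out.ndim else float(out)


def _lab_transfer_inverse(f):
    f = np.asarray(f, dtype=np.float64)
    knot = 6.0 / 29.0
    return np.where(f > knot, f**3, (f - _LINEAR_OFFSET) / _LINEAR_SLOPE)


def xyz_to_lab(xyz_normalized) -> np.ndarray:
    """Convert white-point-normalized XYZ to CIELAB."""
    xyz = _as_color_array(xyz_normalized, "normalized xyz")
    f = lab_transfer(xyz)
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * fy - 16.0
    lab[..., 1] = 500.0 * (fx - fy)
    lab[..., 2] = 200.0 * (fy - fz)
    return lab


def rgb_to_lab(img, *, gamma: bool = False) -> np.ndarray:
    """Full conversion chain: RGB → XYZ → D65-normalized → CIELAB."""
    return xyz_to_lab(normalize_d65(rgb_to_xyz(img, gamma=gamma)))


def lab_to_rgb(lab, *, gamma: bool = False) -> np.ndarray:
    """Algebraic inverse of :func:`rgb_to_lab`; out-of-gamut results are clipped.

    A warning is logged when clipping moves any channel by more than 1e-9.
    """
    lab = _as_color_array(lab, "lab")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack(
        [_lab_transfer_inverse(fx), _lab_transfer_inverse(fy), _lab_transfer_inverse(fz)],
        axis=-1,
    )
    xyz *= D65_WHITE
    rgb = xyz @ np.linalg.inv(RGB_TO_XYZ_MATRIX).T
    if gamma:
        rgb = srgb_gamma_compress(rgb)
    clipped = np.clip(rgb, 0.0, 1.0)
    excess = np.abs(rgb - clipped).max()
    if excess > 1e-9:
        logger.warning("lab_to_rgb clipped out-of-gamut values (max excursion %.4g)", excess)
    return clipped


def lab_to_hue_chroma(lab) -> np.ndarray:
    """Polar coordinates of the (a*, b*) plane.

    Returns a ``(..., 2)`` array of ``(h, C*)`` with the hue angle ``h`` in
    degrees in ``[0, 360)`` from the four-quadrant arctangent, and the chroma
    ``C* = sqrt(a*^2 + b*^2)``.  Achromatic pixels (``C* = 0``) get ``h = 0``
    by convention.
    """
    lab = _as_color_array(lab, "lab")
    a, b = lab[..., 1], lab[..., 2]
    chroma = np.hypot(a, b)
    hue = np.degrees(np.arctan2(b, a)) % 360.0
    hue = np.where(chroma == 0.0, 0.0, hue)
    return np.stack([hue, chroma], axis=-1)
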