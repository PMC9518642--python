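"""Watershed segmentation by immersion of the grayscale topography.

The grayscale raster is treated as a height field and flooded bottom-up from
its regional minima.  Levels are processed in increasing order; at each level
the existing basins grow into the new pixels by synchronous breadth-first
waves (geodesic-distance ordering on plateaus).  A pixel reached by two or
more distinct basins in the same wave becomes a watershed-line pixel
(label 0).  Connected plateaus that no basin reaches are new regional minima
and seed new basins.

The algorithm runs directly on the grayscale values — the heavy circular
smoothing upstream acts as the over-segmentation control, so no gradient
pre-step is applied.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

WATERSHED_LINE = 0

_OFFSETS_4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_OFFSETS_8 = _OFFSETS_4 + ((-1, -1), (-1, 1), (1, -1), (1, 1))


def _offsets(connectivity: int):
    if connectivity == 4:
        return _OFFSETS_4
    if connectivity == 8:
        return _OFFSETS_8
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)


def _shift(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Shift so that out[r, c] = arr[r + dr, c + dc], filling the border."""
    out = np.full_like(arr, fill)
    h, w = arr.shape
    rs_src = slice(max(dr, 0), h + min(dr, 0))
    cs_src = slice(max(dc, 0), w + min(dc, 0))
    rs_dst = slice(max(-dr, 0), h + min(-dr, 0))
    cs_dst = slice(max(-dc, 0), w + min(-dc, 0))
    out[rs_dst, cs_dst] = arr[rs_src, cs_src]
    return out


def watershed_immersion(gray, connectivity: int = 8) -> np.ndarray:
    """Segment a grayscale raster into basins by simulated immersion.

    Parameters
    ----------
    gray
        2-D integer raster with values in ``[0, 255]``.
    connectivity
        Pixel adjacency, 4 or 8 (default 8).

    Returns
    -------
    numpy.ndarray
        Integer label map of the same shape: basins are labelled ``1..N`` in
        flooding order, watershed-line pixels are 0.
    """
    arr = np.asarray(gray)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D grayscale raster, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("grayscale values must lie in [0, 255]")
    arr = arr.astype(np.int64)
    offsets = _offsets(connectivity)
    structure = _structure(connectivity)

    label = np.full(arr.shape, -1, dtype=np.int64)  # -1 = not yet flooded
    assigned = np.zeros(arr.shape, dtype=bool)
    next_label = 1

    for level in np.unique(arr):
        in_level = arr == level

        # Expansion: grow existing basins into the level, one geodesic wave
        # at a time.  Watershed pixels carry reachability but no basin label.
        while True:
            cand = in_level & ~assigned
            if not cand.any():
                break
            any_nb = np.zeros(arr.shape, dtype=bool)
            min_lab = np.full(arr.shape, np.iinfo(np.int64).max, dtype=np.int64)
            max_lab = np.full(arr.shape, -1, dtype=np.int64)
            for dr, dc in offsets:
                nb_assigned = _shift(assigned, dr, dc, False)
                nb_label = _shift(label, dr, dc, -1)
                reach = cand & nb_assigned
                any_nb |= reach
                basin_nb = reach & (nb_label > 0)
                min_lab = np.where(basin_nb, np.minimum(min_lab, nb_label), min_lab)
                max_lab = np.where(basin_nb, np.maximum(max_lab, nb_label), max_lab)
            wave = cand & any_nb
            if not wave.any():
                break
            # one distinct basin → join it; several (or none, i.e. only
            # watershed neighbours) → watershed line
            single = wave & (max_lab > 0) & (min_lab == max_lab)
            label[wave] = WATERSHED_LINE
            label[single] = min_lab[single]
            assigned |= wave

        # Seed phase: unreached plateaus are regional minima → new basins.
        remaining = in_level & ~assigned
        if remaining.any():
            comp, n_comp = ndimage.label(remaining, structure=structure)
            label[remaining] = comp[remaining] + next_label - 1
            next_label += n_comp
            assigned |= remaining

    return label


def region_sizes(labels) -> np.ndarray:
    """Pixel counts of basins ``1..N``; watershed-line pixels are excluded."""
    arr = np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D label map, got shape {arr.shape}")
    n = int(arr.max())
    if n < 1:
        raise ValueError("label map contains no basins")
    counts = np.bincount(arr[arr > 0].ravel(), minlength=n + 1)[1:]
    if np.any(counts == 0):
        raise ValueError("basin labels must form a contiguous range 1..N")
    return counts
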