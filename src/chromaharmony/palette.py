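"""Dominant-color palette construction by K-means clustering in CIELAB.

Clustering runs Lloyd's algorithm on the per-pixel ``(L*, a*, b*)`` vectors
with k-means++ seeding.  Internally, pixels are collapsed to unique colors
with multiplicities, which makes the algorithm exact and fast on images with
few distinct colors.  The palette is rendered as a horizontal strip whose
segment widths are proportional to cluster pixel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from chromaharmony import colorspace

DEFAULT_CLUSTERS = 8
MAX_ITER = 300
CONVERGENCE_TOL = 1e-6


@dataclass(frozen=True)
class Palette:
    """Ordered dominant colors with pixel counts.

    ``centroids`` is a ``(j, 3)`` array of CIELAB colors, ``counts`` the
    matching pixel counts.  Entries are ordered by descending count, ties
    broken by L*, then a*, then b*.
    """

    centroids: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=np.float64))
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        if self.centroids.ndim != 2 or self.centroids.shape[1] != 3:
            raise ValueError("centroids must have shape (j, 3)")
        if self.counts.shape != (self.centroids.shape[0],):
            raise ValueError("counts must have one entry per centroid")
        if self.centroids.shape[0] < 1:
            raise ValueError("palette needs at least one color")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def j(self) -> int:
        return self.centroids.shape[0]

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def _order_palette(centroids: np.ndarray, counts: np.ndarray) -> Palette:
    # Descending count; ties by L*, a*, b* ascending. lexsort: last key primary.
    order = np.lexsort(
        (centroids[:, 2], centroids[:, 1], centroids[:, 0], -counts)
    )
    return Palette(centroids[order], counts[order])


def _kmeanspp_init(points: np.ndarray, weights: np.ndarray, j: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    prob = weights / weights.sum()
    centroids = np.empty((j, 3))
    centroids[0] = points[rng.choice(n, p=prob)]
    d2 = np.sum((points - centroids[0]) ** 2, axis=1)
    for k in range(1, j):
        mass = weights * d2
        total = mass.sum()
        if total <= 0.0:  # all points coincide with chosen centroids
            centroids[k] = points[rng.choice(n, p=prob)]
            continue
        centroids[k] = points[rng.choice(n, p=mass / total)]
        d2 = np.minimum(d2, np.sum((points - centroids[k]) ** 2, axis=1))
    return centroids


def _collapse_duplicates(centroids: np.ndarray, counts: np.ndarray, tol: float = 1e-9):
    kept_c: list[np.ndarray] = []
    kept_n: list[int] = []
    for c, n in zip(centroids, counts):
        for idx, kc in enumerate(kept_c):
            if np.all(np.abs(kc - c) <= tol):
                kept_n[idx] += int(n)
                break
        else:
            kept_c.append(c)
            kept_n.append(int(n))
    return np.array(kept_c), np.array(kept_n, dtype=np.int64)


def kmeans_palette(
    lab,
    j: int = DEFAULT_CLUSTERS,
    seed: int | None = 0,
    history: list[float] | None = None,
) -> Palette:
    """Cluster the pixels of a CIELAB raster into ``j`` dominant colors.

    Lloyd's algorithm: assign each pixel to the nearest centroid by Euclidean
    distance, recompute centroids as cluster means, iterate until the largest
    centroid movement falls below ``1e-6`` or 300 iterations.  Empty clusters
    are re-seeded at the point farthest from its assigned centroid.  If the
    image holds fewer than ``j`` distinct colors, duplicate clusters collapse
    and the actual number is reported.

    Parameters
    ----------
    lab
        ``(H, W, 3)`` CIELAB raster (or ``(N, 3)`` list of colors).
    j
        Requested number of clusters (≥ 1).
    seed
        Seed for the k-means++ initialization; fixed seed ⇒ bit-reproducible.
    history
        If a list is passed, the clustering objective (weighted sum of squared
        distances) after each assignment step is appended to it.
    """
    if j < 1:
        raise ValueError(f"cluster count must be >= 1, got {j}")
    arr = np.asarray(lab, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        pixels = arr.reshape(-1, 3)
    elif arr.ndim == 2 and arr.shape[-1] == 3:
        pixels = arr
    else:
        raise ValueError(f"expected (H, W, 3) or (N, 3) CIELAB input, got shape {arr.shape}")
    if pixels.shape[0] == 0:
        raise ValueError("cannot build a palette from an empty image")

    points, weights = np.unique(pixels, axis=0, return_counts=True)
    weights = weights.astype(np.float64)
    n_distinct = points.shape[0]

    if n_distinct <= j:
        # each distinct color is its own (exact) cluster
        return _order_palette(points.copy(), weights.astype(np.int64))

    rng = np.random.default_rng(seed)
    centroids = _kmeanspp_init(points, weights, j, rng)

    for _ in range(MAX_ITER):
        # (n_distinct, j) squared distances
        d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        if history is not None:
            history.append(float((weights * d2[np.arange(n_distinct), assign]).sum()))
        new_centroids = centroids.copy()
        for k in range(j):
            mask = assign == k
            if mask.any():
                w = weights[mask]
                new_centroids[k] = (points[mask] * w[:, None]).sum(axis=0) / w.sum()
            else:
                # re-seed at the point farthest from its current centroid
                farthest = d2[np.arange(n_distinct), assign].argmax()
                new_centroids[k] = points[farthest]
        movement = np.abs(new_centroids - centroids).max()
        centroids = new_centroids
        if movement < CONVERGENCE_TOL:
            break

    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1)
    counts = np.bincount(assign, weights=weights, minlength=j).astype(np.int64)
    centroids, counts = _collapse_duplicates(centroids, counts)
    keep = counts > 0
    return _order_palette(centroids[keep], counts[keep])


def kmeans_objective(lab, palette: Palette) -> float:
    """Sum of squared distances of every pixel to its nearest palette color."""
    pixels = np.asarray(lab, dtype=np.float64).reshape(-1, 3)
    d2 = ((pixels[:, None, :] - palette.centroids[None, :, :]) ** 2).sum(axis=2)
    return float(d2.min(axis=1).sum())


def largest_remainder_widths(counts, total_width: int) -> np.ndarray:
    """Apportion ``total_width`` pixels proportionally to ``counts``.

    Largest-remainder rounding; remainder ties go to the earlier entry.
    """
    counts = np.asarray(counts, dtype=np.float64)
    ideal = counts / counts.sum() * total_width
    widths = np.floor(ideal).astype(np.int64)
    remainder = ideal - widths
    missing = int(total_width - widths.sum())
    if missing > 0:
        order = np.lexsort((np.arange(len(counts)), -remainder))
        widths[order[:missing]] += 1
    return widths


def render_palette(p: Palette, width: int, height: int) -> np.ndarray:
    """Render the palette as a horizontal RGB strip with proportional segments."""
    if width < 1 or height < 1:
        raise ValueError("strip dimensions must be positive")
    widths = largest_remainder_widths(p.counts, width)
    rgb_colors = colorspace.lab_to_rgb(p.centroids)
    strip = np.zeros((height, width, 3))
    x = 0
    for color, w in zip(rgb_colors, widths):
        strip[:, x : x + w] = color
        x += w
    return strip
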