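"""Independent brute-force oracles used to cross-check the package.

Everything here is written against the *definitions* (explicit loops over
pixels, sets and dicts, no vectorization) and deliberately shares no code
with the implementation under test.
"""

from __future__ import annotations

import numpy as np


def neighbor_offsets(connectivity: int):
    four = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 4:
        return four
    if connectivity == 8:
        return four + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    raise ValueError(connectivity)


def neighbor_mean_sq_diff_loop(raster, connectivity: int = 8) -> float:
    """Double loop over every pixel and each in-image neighbor (ordered pairs)."""
    arr = np.asarray(raster, dtype=float)
    h, w = arr.shape
    total = 0.0
    pairs = 0
    for r in range(h):
        for c in range(w):
            for dr, dc in neighbor_offsets(connectivity):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w:
                    total += (arr[r, c] - arr[rr, cc]) ** 2
                    pairs += 1
    if pairs == 0:
        return 0.0
    return total / pairs


def watershed_flood_loop(gray, connectivity: int = 8) -> np.ndarray:
    """Level-by-level immersion simulated with sets and dicts.

    For each grayscale level in increasing order: existing basins (and
    watershed pixels) expand into the level's pixels by synchronous
    breadth-first waves; a pixel reached by exactly one basin joins it, a
    pixel reached by several basins — or only by watershed pixels — becomes a
    watershed-line pixel (0).  Pixels of the level that no wave reaches form
    new regional minima; their connected components seed new basins in raster
    order of first appearance.
    """
    arr = np.asarray(gray)
    h, w = arr.shape
    offsets = neighbor_offsets(connectivity)

    def neighbors(p):
        r, c = p
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                yield (rr, cc)

    label: dict[tuple[int, int], int] = {}
    next_label = 1

    for level in sorted({int(v) for v in arr.ravel()}):
        unassigned = {
            (r, c) for r in range(h) for c in range(w) if arr[r, c] == level
        }
        # expansion waves
        while True:
            frontier: dict[tuple[int, int], set[int]] = {}
            for p in unassigned:
                basins = set()
                reached = False
                for q in neighbors(p):
                    if q in label:
                        reached = True
                        if label[q] > 0:
                            basins.add(label[q])
                if reached:
                    frontier[p] = basins
            if not frontier:
                break
            for p, basins in frontier.items():
                label[p] = basins.pop() if len(basins) == 1 else 0
            unassigned -= frontier.keys()
        # unreached plateaus are new minima; components in raster order
        for r in range(h):
            for c in range(w):
                if (r, c) in unassigned:
                    stack = [(r, c)]
                    unassigned.discard((r, c))
                    label[(r, c)] = next_label
                    while stack:
                        p = stack.pop()
                        for q in neighbors(p):
                            if q in unassigned:
                                unassigned.discard(q)
                                label[q] = next_label
                                stack.append(q)
                    next_label += 1

    out = np.zeros((h, w), dtype=np.int64)
    for (r, c), lab in label.items():
        out[r, c] = lab
    return out


def regional_minima(gray, connectivity: int = 8) -> list[set]:
    """Connected plateaus with no strictly lower neighbor."""
    arr = np.asarray(gray)
    h, w = arr.shape
    offsets = neighbor_offsets(connectivity)
    seen = set()
    minima = []
    for r in range(h):
        for c in range(w):
            if (r, c) in seen:
                continue
            v = arr[r, c]
            comp = {(r, c)}
            stack = [(r, c)]
            is_min = True
            while stack:
                pr, pc = stack.pop()
                for dr, dc in offsets:
                    rr, cc = pr + dr, pc + dc
                    if not (0 <= rr < h and 0 <= cc < w):
                        continue
                    if arr[rr, cc] == v and (rr, cc) not in comp:
                        comp.add((rr, cc))
                        stack.append((rr, cc))
                    elif arr[rr, cc] < v:
                        is_min = False
            seen |= comp
            if is_min:
                minima.append(comp)
    return minima


def circular_mean_loop(channel, radius: int) -> np.ndarray:
    """Direct per-pixel disk average with border renormalization."""
    arr = np.asarray(channel, dtype=float)
    h, w = arr.shape
    out = np.empty_like(arr)
    for r in range(h):
        for c in range(w):
            acc = 0.0
            n = 0
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if dr * dr + dc * dc <= radius * radius:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w:
                            acc += arr[rr, cc]
                            n += 1
            out[r, c] = acc / n
    return out
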