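"""Independent brute-force reference implementations used as test oracles.

These deliberately use plain Python data structures (dicts, sets, loops)
rather than the vectorized/union-find code paths of the package, so that
agreement between the two is meaningful.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def relabel_reference(assignments: list[int], h: int, w: int) -> np.ndarray:
    """First-occurrence renumbering, written independently with a dict."""
    mapping: dict[int, int] = {}
    out = np.empty((h, w), dtype=np.int64)
    i = 0
    for r in range(h):
        for c in range(w):
            a = assignments[r * w + c]
            if a not in mapping:
                mapping[a] = len(mapping)
            out[r, c] = mapping[a]
            i += 1
    return out


# ---------------------------------------------------------------------------
# Felzenszwalb reference: explicit component sets, one merge at a time

def felzenszwalb_reference(rgb: np.ndarray, scale_k: float, min_size: int) -> np.ndarray:
    """Graph merging with the pairwise region-comparison predicate on the
    4-connected grid (no smoothing; callers pass sigma=0 inputs)."""
    h, w = rgb.shape[:2]
    n = h * w
    edges = []
    for r in range(h):
        for c in range(w):
            a = r * w + c
            if c + 1 < w:
                wgt = math.sqrt(sum((rgb[r, c, k] - rgb[r, c + 1, k]) ** 2 for k in range(3)))
                edges.append((wgt, a, a + 1))
            if r + 1 < h:
                wgt = math.sqrt(sum((rgb[r, c, k] - rgb[r + 1, c, k]) ** 2 for k in range(3)))
                edges.append((wgt, a, a + w))
    edges.sort()

    comp_of = list(range(n))
    comps: dict[int, set[int]] = {i: {i} for i in range(n)}
    internal: dict[int, float] = {i: 0.0 for i in range(n)}

    def union(ia: int, ib: int, wgt: float) -> None:
        keep, drop = (ia, ib) if ia < ib else (ib, ia)
        for px in comps[drop]:
            comp_of[px] = keep
        comps[keep] |= comps.pop(drop)
        internal[keep] = wgt
        internal.pop(drop)

    for wgt, a, b in edges:
        ia, ib = comp_of[a], comp_of[b]
        if ia == ib:
            continue
        if wgt <= min(
            internal[ia] + scale_k / len(comps[ia]),
            internal[ib] + scale_k / len(comps[ib]),
        ):
            union(ia, ib, wgt)

    while min_size > 1 and len(comps) > 1:
        small = sorted((len(comps[i]), i) for i in comps if len(comps[i]) < min_size)
        if not small:
            break
        _, target = small[0]
        for wgt, a, b in edges:
            ia, ib = comp_of[a], comp_of[b]
            if ia != ib and (ia == target or ib == target):
                union(ia, ib, max(wgt, internal[ia], internal[ib]))
                break

    return relabel_reference(comp_of, h, w)


# ---------------------------------------------------------------------------
# Quickshift reference: O(N^2) density and linking over a supplied feature
# image (color channels already converted/scaled by the caller)

def quickshift_reference(
    color: np.ndarray, kernel_size: float, max_dist: float
) -> np.ndarray:
    h, w = color.shape[:2]
    r = int(math.ceil(3.0 * kernel_size))
    k2 = 2.0 * kernel_size**2

    density = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            total = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    yy, xx = y + dy, x + dx
                    if not (0 <= yy < h and 0 <= xx < w):
                        continue
                    d2 = dy * dy + dx * dx
                    for k in range(color.shape[2]):
                        d2 += (color[y, x, k] - color[yy, xx, k]) ** 2
                    total += math.exp(-d2 / k2)
            density[y, x] = total

    rmax = int(math.floor(max_dist))
    offsets = sorted(
        (dy * dy + dx * dx, dy, dx)
        for dy in range(-rmax, rmax + 1)
        for dx in range(-rmax, rmax + 1)
        if 0 < dy * dy + dx * dx <= max_dist**2
    )
    parent = list(range(h * w))
    for y in range(h):
        for x in range(w):
            for _, dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if 0 <= yy < h and 0 <= xx < w and density[yy, xx] > density[y, x]:
                    parent[y * w + x] = yy * w + xx
                    break

    def root(i: int) -> int:
        seen = set()
        while parent[i] != i:
            assert i not in seen
            seen.add(i)
            i = parent[i]
        return i

    return relabel_reference([root(i) for i in range(h * w)], h, w), density, parent


# ---------------------------------------------------------------------------
# flood fill reference: breadth-first search from the seed

def bfs_flood_fill(rgb: np.ndarray, seed: tuple[int, int], tolerance: float) -> set:
    h, w = rgb.shape[:2]
    sr, sc = seed
    seed_color = rgb[sr, sc]

    def admissible(r, c):
        return (
            math.sqrt(sum((rgb[r, c, k] - seed_color[k]) ** 2 for k in range(3)))
            <= tolerance
        )

    visited = {(sr, sc)}
    queue = deque([(sr, sc)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and (rr, cc) not in visited:
                if admissible(rr, cc):
                    visited.add((rr, cc))
                    queue.append((rr, cc))
    return visited


# ---------------------------------------------------------------------------
# discrete Gaussian convolution with reflective padding (1-D, per row)

def gaussian_reference_row(row: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    xs = np.arange(-radius, radius + 1)
    kernel = np.exp(-(xs**2) / (2.0 * sigma**2))
    kernel /= kernel.sum()
    n = len(row)
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j, kv in zip(range(i - radius, i + radius + 1), kernel):
            # reflect: ...(b a | a b c)... i.e. index -1 -> 0, n -> n-1
            while j < 0 or j >= n:
                if j < 0:
                    j = -j - 1
                else:
                    j = 2 * n - j - 1
            acc += kv * row[j]
        out[i] = acc
    return out


# ---------------------------------------------------------------------------
# spatial Voronoi assignment with first-wins tie-break (SLIC degenerate case)

def spatial_voronoi(h: int, w: int, centers: list[tuple[float, float]]) -> np.ndarray:
    out = np.empty((h, w), dtype=np.int64)
    for r in range(h):
        for c in range(w):
            d2 = [(r - cy) ** 2 + (c - cx) ** 2 for cy, cx in centers]
            out[r, c] = int(np.argmin(d2))
    return out
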