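"""Superpixel proposal generators: Felzenszwalb, SLIC and Quickshift.

All three are deterministic: identical image and parameters give identical
partitions.  Segment ids are contiguous from 0 and ordered by first
row-major pixel occurrence.

Defaults declared here are the package's own (the algorithms' original
publications do not prescribe them):

* Felzenszwalb runs on Gaussian-smoothed RGB with a 4-connected grid graph;
  equal-weight edges are ordered by (weight, first endpoint, second
  endpoint) linear index.
* SLIC and Quickshift run in CIELAB, as the cited methods do.
* Quickshift truncates the Parzen density sum at a square spatial window of
  half-width ceil(3 * kernel_size).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DomainError
from .imagecore import RasterImage, Rect, gaussian_smooth, to_lab

__all__ = [
    "SuperpixelMap",
    "FelzParams",
    "SlicParams",
    "QuickshiftParams",
    "felzenszwalb_segment",
    "slic_segment",
    "quickshift_segment",
    "relabel_by_occurrence",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ---------------------------------------------------------------------------
# container

class SuperpixelMap:
    """An H x W partition of an image into contiguously-numbered segments.

    ``region`` records the sub-image rectangle the proposal was computed on
    (None means the full session image); the labeling module uses it to
    offset segment selections back into full-image coordinates.
    """

    __slots__ = ("labels", "region")

    def __init__(self, labels: np.ndarray, region: Rect | None = None, copy: bool = True):
        arr = np.array(labels, dtype=np.int32, copy=copy)
        if arr.ndim != 2:
            raise DomainError(f"expected an HxW label array, got shape {arr.shape}")
        if arr.size == 0:
            raise DomainError("empty superpixel map")
        if arr.min() < 0:
            raise DomainError("segment ids must be nonnegative")
        n = int(arr.max()) + 1
        present = np.bincount(arr.ravel(), minlength=n)
        if (present == 0).any():
            raise DomainError("segment ids must be contiguous from 0")
        self.labels = arr
        self.region = region

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def n_segments(self) -> int:
        return int(self.labels.max()) + 1

    def segment_mask(self, segment_id: int) -> np.ndarray:
        if not (0 <= segment_id < self.n_segments):
            raise DomainError(f"segment id {segment_id} not in [0, {self.n_segments})")
        return self.labels == segment_id

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, SuperpixelMap)
            and np.array_equal(self.labels, other.labels)
            and self.region == other.region
        )


def relabel_by_occurrence(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary integer labels to 0..n-1 in row-major first-occurrence order."""
    flat = labels.ravel()
    uniq, first, inverse = np.unique(flat, return_index=True, return_inverse=True)
    order = np.argsort(first, kind="stable")
    rank = np.empty(len(uniq), dtype=np.int32)
    rank[order] = np.arange(len(uniq), dtype=np.int32)
    return rank[inverse].reshape(labels.shape)


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class FelzParams:
    """Graph-merging controls: threshold constant k, pre-smoothing sigma,
    and the minimum final segment size in pixels."""

    scale_k: float = 0.5
    sigma: float = 0.8
    min_size: int = 20

    def __post_init__(self):
        if not (self.scale_k > 0):
            raise DomainError("scale_k must be positive")
        if self.sigma < 0:
            raise DomainError("sigma must be nonnegative")
        if self.min_size < 1:
            raise DomainError("min_size must be >= 1")


@dataclass(frozen=True)
class SlicParams:
    """Requested cluster count, spatial-vs-color weight m (compactness,
    on the CIELAB scale), iteration cap, and connectivity enforcement."""

    n_segments: int = 100
    compactness: float = 10.0
    max_iter: int = 10
    enforce_connectivity: bool = True

    def __post_init__(self):
        if self.n_segments < 1:
            raise DomainError("n_segments must be >= 1")
        if not (self.compactness > 0):
            raise DomainError("compactness must be positive")
        if self.max_iter < 1:
            raise DomainError("max_iter must be >= 1")


@dataclass(frozen=True)
class QuickshiftParams:
    """Parzen bandwidth (pixels/feature units), maximum parent-link
    distance (pixels), and the color-vs-space ratio scaling CIELAB."""

    kernel_size: float = 3.0
    max_dist: float = 6.0
    ratio: float = 0.5

    def __post_init__(self):
        if not (self.kernel_size > 0):
            raise DomainError("kernel_size must be positive")
        if not (self.max_dist > 0):
            raise DomainError("max_dist must be positive")
        if not (0 < self.ratio <= 1):
            raise DomainError("ratio must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Felzenszwalb efficient graph-based segmentation

class _UnionFind:
    __slots__ = ("parent", "size", "internal")

    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)
        self.internal = np.zeros(n, dtype=np.float64)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:  # path compression
            p[i], i = root, p[i]
        return int(root)

    def union(self, a: int, b: int, weight: float) -> int:
        """Merge roots a and b; the smaller index becomes the root."""
        root, child = (a, b) if a < b else (b, a)
        self.parent[child] = root
        self.size[root] += self.size[child]
        # edges arrive in nondecreasing order, so the joining edge is the
        # largest edge inside the merged component
        self.internal[root] = weight
        return root


def _grid_edges(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """4-connected grid edges (a, b, weight) with Euclidean color weights."""
    h, w = data.shape[:2]
    idx = np.arange(h * w, dtype=np.int64).reshape(h, w)
    ah = idx[:, :-1].ravel()
    bh = idx[:, 1:].ravel()
    wh = np.sqrt(((data[:, :-1] - data[:, 1:]) ** 2).sum(axis=2)).ravel()
    av = idx[:-1, :].ravel()
    bv = idx[1:, :].ravel()
    wv = np.sqrt(((data[:-1, :] - data[1:, :]) ** 2).sum(axis=2)).ravel()
    return (
        np.concatenate([ah, av]),
        np.concatenate([bh, bv]),
        np.concatenate([wh, wv]),
    )


def felzenszwalb_segment(img: RasterImage, params: FelzParams | None = None) -> SuperpixelMap:
    """Greedy graph merging with the pairwise region-comparison predicate.

    Edges of the 4-connected grid over smoothed RGB pixels are processed in
    nondecreasing weight order; components C1, C2 merge when the connecting
    edge weight is at most min over i of Int(Ci) + scale_k/|Ci|, where
    Int(C) is the largest edge weight already merged inside C.  Components
    smaller than min_size are then folded into their most-similar neighbor.
    """
    p = params or FelzParams()
    data = gaussian_smooth(img, p.sigma).data
    h, w = data.shape[:2]
    n = h * w
    ea, eb, ew = _grid_edges(data)
    order = np.lexsort((eb, ea, ew))  # (weight, a, b) deterministic tie-break
    ea, eb, ew = ea[order], eb[order], ew[order]

    uf = _UnionFind(n)
    k = p.scale_k
    for i in range(len(ew)):
        ra = uf.find(int(ea[i]))
        rb = uf.find(int(eb[i]))
        if ra == rb:
            continue
        weight = float(ew[i])
        if weight <= min(
            uf.internal[ra] + k / uf.size[ra],
            uf.internal[rb] + k / uf.size[rb],
        ):
            uf.union(ra, rb, weight)

    _merge_small_components(uf, ea, eb, ew, n, p.min_size)

    roots = _resolve_roots(uf.parent)
    return SuperpixelMap(relabel_by_occurrence(roots.reshape(h, w)), copy=False)


def _resolve_roots(parent: np.ndarray) -> np.ndarray:
    roots = parent.copy()
    while True:
        nxt = parent[roots]
        if np.array_equal(nxt, roots):
            return roots
        roots = nxt


def _merge_small_components(uf, ea, eb, ew, n, min_size):
    """Fold components below min_size into their most-similar neighbor.

    One merge at a time: the smallest undersized component (ties by lowest
    root label, which is the component's lowest pixel index) is joined
    across its minimum-weight outgoing edge (ties by edge order)."""
    if min_size <= 1:
        return
    while True:
        roots = _resolve_roots(uf.parent)
        sizes = np.bincount(roots, minlength=n)
        comp_ids = np.unique(roots)
        if len(comp_ids) == 1:
            return
        small = comp_ids[sizes[comp_ids] < min_size]
        if len(small) == 0:
            return
        target = small[np.lexsort((small, sizes[small]))[0]]
        ra_all, rb_all = roots[ea], roots[eb]
        outgoing = (ra_all != rb_all) & ((ra_all == target) | (rb_all == target))
        idx = np.nonzero(outgoing)[0]
        if len(idx) == 0:  # unreachable on a connected grid graph
            return
        i = int(idx[0])  # edges pre-sorted by (weight, a, b)
        ra, rb = int(ra_all[i]), int(rb_all[i])
        uf.union(ra, rb, max(float(ew[i]), uf.internal[ra], uf.internal[rb]))


# ---------------------------------------------------------------------------
# SLIC

def _slic_grid_shape(n_segments: int, h: int, w: int) -> tuple[int, int]:
    """Rows x cols of seed grid: closest product to n_segments, squarest cells."""
    best = None
    for ny in range(1, min(n_segments, h) + 1):
        nx = min(max(1, round(n_segments / ny)), w)
        score = (abs(ny * nx - n_segments), abs(w / nx - h / ny))
        if best is None or score < best[0]:
            best = (score, ny, nx)
    return best[1], best[2]


def _seed_centers(lab: np.ndarray, ny: int, nx: int) -> np.ndarray:
    """Grid seeds moved to the lowest-gradient pixel in their 3x3 neighborhood.

    Ties prefer the unperturbed position, then row-major order, so seeds on a
    constant image stay on the regular grid.
    """
    h, w = lab.shape[:2]
    gy = np.gradient(lab, axis=0)
    gx = np.gradient(lab, axis=1)
    grad = (gy**2 + gx**2).sum(axis=2)
    centers = np.empty((ny * nx, 5), dtype=np.float64)
    k = 0
    for iy in range(ny):
        for ix in range(nx):
            r0 = min(h - 1, int((iy + 0.5) * h / ny))
            c0 = min(w - 1, int((ix + 0.5) * w / nx))
            cand = [
                (grad[r, c], (r - r0) ** 2 + (c - c0) ** 2, r, c)
                for r in range(max(0, r0 - 1), min(h, r0 + 2))
                for c in range(max(0, c0 - 1), min(w, c0 + 2))
            ]
            _, _, r, c = min(cand)
            centers[k] = (*lab[r, c], r, c)
            k += 1
    return centers


def slic_segment(
    img: RasterImage,
    params: SlicParams | None = None,
    *,
    return_trace: bool = False,
):
    """Local k-means in (L, a, b, y, x) with grid seeding.

    Pixels are assigned to the nearest center among those whose 2S x 2S
    search window covers them (S = sqrt(H*W/n_segments)), using the squared
    distance d_lab^2 + (m/S)^2 * d_xy^2; centers are then recomputed as the
    mean labxy vector of their pixels.  The per-iteration total squared
    assignment cost is non-increasing and is returned when ``return_trace``.
    """
    p = params or SlicParams()
    h, w = img.height, img.width
    if p.n_segments > h * w:
        raise DomainError(f"n_segments={p.n_segments} exceeds pixel count {h * w}")
    lab = to_lab(img).data
    s = math.sqrt(h * w / p.n_segments)
    ny, nx = _slic_grid_shape(p.n_segments, h, w)
    centers = _seed_centers(lab, ny, nx)
    n_centers = len(centers)
    w2 = (p.compactness / s) ** 2
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    labels = np.full((h, w), -1, dtype=np.int32)
    costs: list[float] = []
    for _ in range(p.max_iter):
        if labels[0, 0] >= 0:
            # keep the current assignment in the candidate set: the
            # alternating objective then never increases
            cc = centers[labels]
            best = ((lab - cc[..., :3]) ** 2).sum(axis=2) + w2 * (
                (yy - cc[..., 3]) ** 2 + (xx - cc[..., 4]) ** 2
            )
            new_labels = labels.copy()
        else:
            best = np.full((h, w), np.inf)
            new_labels = np.full((h, w), -1, dtype=np.int32)
        for k in range(n_centers):
            cl, ca, cb, cy, cx = centers[k]
            r0 = max(0, int(math.floor(cy - s)))
            r1 = min(h, int(math.ceil(cy + s)) + 1)
            c0 = max(0, int(math.floor(cx - s)))
            c1 = min(w, int(math.ceil(cx + s)) + 1)
            if r0 >= r1 or c0 >= c1:
                continue
            win = lab[r0:r1, c0:c1]
            d2 = (
                (win[..., 0] - cl) ** 2
                + (win[..., 1] - ca) ** 2
                + (win[..., 2] - cb) ** 2
                + w2 * ((yy[r0:r1, c0:c1] - cy) ** 2 + (xx[r0:r1, c0:c1] - cx) ** 2)
            )
            upd = d2 < best[r0:r1, c0:c1]
            best[r0:r1, c0:c1][upd] = d2[upd]
            new_labels[r0:r1, c0:c1][upd] = k
        if (new_labels < 0).any():
            # pixels outside every window (coarse grids): nearest center overall
            rows, cols = np.nonzero(new_labels < 0)
            d2 = (
                ((lab[rows, cols][:, None, :] - centers[None, :, :3]) ** 2).sum(axis=2)
                + w2
                * (
                    (rows[:, None] - centers[None, :, 3]) ** 2
                    + (cols[:, None] - centers[None, :, 4]) ** 2
                )
            )
            new_labels[rows, cols] = np.argmin(d2, axis=1)
            best[rows, cols] = d2[np.arange(len(rows)), new_labels[rows, cols]]
        changed = not np.array_equal(new_labels, labels)
        labels = new_labels
        costs.append(float(best.sum()))
        # center update: mean labxy per cluster (empty clusters keep position)
        flat = labels.ravel()
        count = np.bincount(flat, minlength=n_centers).astype(np.float64)
        nonempty = count > 0
        for f, feat in enumerate(
            (lab[..., 0], lab[..., 1], lab[..., 2], yy, xx)
        ):
            sums = np.bincount(flat, weights=feat.ravel(), minlength=n_centers)
            centers[nonempty, f] = sums[nonempty] / count[nonempty]
        if not changed:
            break

    if p.enforce_connectivity:
        labels = _enforce_connectivity(labels, min_fragment=s * s / 4.0)
    result = SuperpixelMap(relabel_by_occurrence(labels), copy=False)
    if return_trace:
        return result, costs
    return result


def _enforce_connectivity(labels: np.ndarray, min_fragment: float) -> np.ndarray:
    """Reassign stray 4-connected fragments smaller than ``min_fragment``
    to the adjacent component they share the longest boundary with.

    The largest fragment of each cluster always survives; every returned
    id is 4-connected.
    """
    h, w = labels.shape
    comp = np.zeros((h, w), dtype=np.int64)
    n_comp = 0
    for v in np.unique(labels):
        lab_comp, nc = ndimage.label(labels == v, structure=_FOUR_CONN)
        comp[labels == v] = lab_comp[labels == v] + n_comp - 1
        n_comp += nc
    comp = relabel_by_occurrence(comp).astype(np.int64)
    n_comp = int(comp.max()) + 1
    sizes = np.bincount(comp.ravel(), minlength=n_comp)

    # largest fragment per original cluster is never a stray (tie: lowest id)
    keep = np.zeros(n_comp, dtype=bool)
    flat_lab = labels.ravel()
    flat_comp = comp.ravel()
    for v in np.unique(flat_lab):
        comps_v = np.unique(flat_comp[flat_lab == v])
        largest = comps_v[np.argmax(sizes[comps_v])]
        keep[largest] = True

    # component adjacency with boundary-contact counts
    pairs = []
    pa, pb = comp[:, :-1].ravel(), comp[:, 1:].ravel()
    m = pa != pb
    pairs.append(np.stack([np.minimum(pa[m], pb[m]), np.maximum(pa[m], pb[m])], axis=1))
    pa, pb = comp[:-1, :].ravel(), comp[1:, :].ravel()
    m = pa != pb
    pairs.append(np.stack([np.minimum(pa[m], pb[m]), np.maximum(pa[m], pb[m])], axis=1))
    allp = np.concatenate(pairs, axis=0)
    if len(allp) == 0:
        return labels
    uniq_pairs, contact = np.unique(allp, axis=0, return_counts=True)
    adjacency: list[dict[int, int]] = [dict() for _ in range(n_comp)]
    for (a, b), cnt in zip(uniq_pairs.tolist(), contact.tolist()):
        adjacency[a][b] = adjacency[a].get(b, 0) + cnt
        adjacency[b][a] = adjacency[b].get(a, 0) + cnt

    parent = np.arange(n_comp, dtype=np.int64)
    members: dict[int, list[int]] = {c: [c] for c in range(n_comp)}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    strays = sorted(
        (c for c in range(n_comp) if not keep[c] and sizes[c] < min_fragment),
        key=lambda c: (sizes[c], c),
    )
    for c in strays:
        rc = find(c)
        # aggregate contact counts of everything merged into rc, per neighbor root
        weight: dict[int, int] = {}
        for m in members[rc]:
            for nb, cnt in adjacency[m].items():
                rn = find(nb)
                if rn != rc:
                    weight[rn] = weight.get(rn, 0) + cnt
        if not weight:
            continue
        target = max(weight.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        parent[rc] = target
        members[target].extend(members.pop(rc))
    roots = np.fromiter((find(c) for c in range(n_comp)), dtype=np.int64, count=n_comp)
    return roots[comp]


# ---------------------------------------------------------------------------
# Quickshift

def quickshift_segment(
    img: RasterImage, params: QuickshiftParams | None = None
) -> SuperpixelMap:
    """Mode seeking in (ratio * Lab, y, x) with a Gaussian Parzen density.

    Each pixel links to the spatially nearest pixel of strictly higher
    density within ``max_dist``; pixels with no such neighbor are roots and
    segments are the trees of the resulting forest.  The density sum is
    truncated at a square window of half-width ceil(3 * kernel_size).
    """
    p = params or QuickshiftParams()
    h, w = img.height, img.width
    color = to_lab(img).data * p.ratio
    k2 = 2.0 * p.kernel_size**2
    r = int(math.ceil(3.0 * p.kernel_size))

    density = np.zeros((h, w), dtype=np.float64)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            ta, tb, sa, sb = _overlap(h, dy)
            la, lb, ra_, rb_ = _overlap(w, dx)
            if ta >= tb or la >= lb:
                continue
            diff = color[ta:tb, la:lb] - color[sa:sb, ra_:rb_]
            d2 = (diff**2).sum(axis=2) + dy * dy + dx * dx
            density[ta:tb, la:lb] += np.exp(-d2 / k2)

    flat_idx = np.arange(h * w, dtype=np.int64).reshape(h, w)
    parent = flat_idx.copy()
    found = np.zeros((h, w), dtype=bool)
    rmax = int(math.floor(p.max_dist))
    offsets = sorted(
        (
            (dy * dy + dx * dx, dy, dx)
            for dy in range(-rmax, rmax + 1)
            for dx in range(-rmax, rmax + 1)
            if 0 < dy * dy + dx * dx <= p.max_dist**2
        )
    )
    for _, dy, dx in offsets:
        ta, tb, sa, sb = _overlap(h, dy)
        la, lb, ra_, rb_ = _overlap(w, dx)
        if ta >= tb or la >= lb:
            continue
        cand = (~found[ta:tb, la:lb]) & (
            density[sa:sb, ra_:rb_] > density[ta:tb, la:lb]
        )
        parent[ta:tb, la:lb][cand] = flat_idx[sa:sb, ra_:rb_][cand]
        found[ta:tb, la:lb] |= cand

    roots = parent.ravel()
    while True:
        nxt = roots[roots]
        if np.array_equal(nxt, roots):
            break
        roots = nxt
    return SuperpixelMap(relabel_by_occurrence(roots.reshape(h, w)), copy=False)


def _overlap(n: int, d: int) -> tuple[int, int, int, int]:
    """Slice bounds so that target[t0:t1] pairs with source[s0:s1] shifted by d."""
    t0, t1 = max(0, -d), min(n, n - d)
    return t0, t1, t0 + d, t1 + d
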