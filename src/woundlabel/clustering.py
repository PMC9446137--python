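"""K-means segmentation over raw RGB pixel intensities.

Unlike the superpixel generators, clusters here need not be spatially
connected; the labeling module treats each connected component of a
cluster as an independently selectable region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .imagecore import RasterImage
from .superpixels import SuperpixelMap, relabel_by_occurrence

__all__ = ["KMeansParams", "kmeans_segment"]


@dataclass(frozen=True)
class KMeansParams:
    n_clusters: int = 5
    max_iter: int = 100
    n_init: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise DomainError("n_clusters must be >= 1")
        if self.max_iter < 1:
            raise DomainError("max_iter must be >= 1")
        if self.n_init < 1:
            raise DomainError("n_init must be >= 1")


def _kmeans_pp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Standard k-means++ seeding: each new center drawn with probability
    proportional to the squared distance to the nearest chosen center."""
    n = len(x)
    centers = np.empty((k, x.shape[1]), dtype=np.float64)
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0.0:
            idx = int(rng.integers(n))
        else:
            idx = int(rng.choice(n, p=d2 / total))
        centers[j] = x[idx]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(x: np.ndarray, centers: np.ndarray, max_iter: int):
    """Lloyd iterations; returns (labels, sse, per-iteration SSE trace).

    An empty cluster is re-seeded at the point farthest from its assigned
    centroid, keeping the requested cluster count whenever feasible.
    """
    k = len(centers)
    trace: list[float] = []
    labels = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = np.argmin(d2, axis=1)
        point_d2 = d2[np.arange(len(x)), new_labels]
        counts = np.bincount(new_labels, minlength=k)
        for j in np.nonzero(counts == 0)[0]:
            far = int(np.argmax(point_d2))
            new_labels[far] = j
            centers[j] = x[far]
            point_d2[far] = 0.0
            counts = np.bincount(new_labels, minlength=k)
        trace.append(float(point_d2.sum()))
        converged = labels is not None and np.array_equal(new_labels, labels)
        labels = new_labels
        for j in range(k):
            members = x[labels == j]
            if len(members):
                centers[j] = members.mean(axis=0)
        if converged:
            break
    return labels, trace[-1], trace


def kmeans_segment(
    img: RasterImage,
    params: KMeansParams | None = None,
    *,
    return_trace: bool = False,
):
    """Cluster per-pixel RGB vectors with seeded k-means++ / Lloyd.

    Runs ``n_init`` restarts and keeps the lowest within-cluster sum of
    squares; cluster ids are renumbered by first row-major pixel
    occurrence, so a fixed seed gives a bit-identical assignment.  With
    ``return_trace`` also returns the winning restart's per-iteration SSE
    (non-increasing).
    """
    p = params or KMeansParams()
    h, w = img.height, img.width
    if p.n_clusters > h * w:
        raise DomainError(f"n_clusters={p.n_clusters} exceeds pixel count {h * w}")
    x = img.data.reshape(-1, 3)
    best = None
    for restart in range(p.n_init):
        rng = np.random.default_rng([p.seed & 0x7FFFFFFF, restart])
        centers = _kmeans_pp_init(x, p.n_clusters, rng)
        labels, sse, trace = _lloyd(x, centers, p.max_iter)
        if best is None or sse < best[0]:
            best = (sse, labels, trace)
    _, labels, trace = best
    result = SuperpixelMap(relabel_by_occurrence(labels.reshape(h, w)), copy=False)
    if return_trace:
        return result, trace
    return result
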