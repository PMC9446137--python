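"""Seeded synthetic wound scenes with ground-truth tissue masks.

Because clinical wound photographs and their expert labelings are not
freely distributable, this module draws stylized stand-ins: a background
plane, a large skin ellipse, and a wound bed bounded by an irregular
closed curve, whose interior is granulation tissue with embedded slough
and necrotic blobs.  Per-pixel Gaussian color noise and an optional linear
illumination gradient roughen the result.  Everything is deterministic
under the seed, and the constructing class of each pixel is recorded as
ground truth — so proposal generation, selection and evaluation can be
exercised end-to-end with a known answer.

``oracle_select`` models a perfect user: every proposal segment takes the
majority truth class of its pixels, which is exactly the best any
constant-per-segment selection can do for pooled accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DomainError
from .imagecore import RasterImage
from .labeling import LabelMap, TissuePalette
from .superpixels import SuperpixelMap
from .evaluation import ClassMetrics, class_metrics, confusion_matrix
from .labeling import _SEGMENTERS, _PARAM_TYPES

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "generate_scene",
    "oracle_select",
    "achievable_metrics",
    "fixture_scene_params",
]

# Stylized clinical hues (RGB in [0,1]): cool blue-gray backdrop, tan skin,
# red granulation, yellow slough, near-black eschar.
_DEFAULT_COLORS = {
    "background": (0.42, 0.47, 0.55),
    "intact_skin": (0.82, 0.62, 0.45),
    "granulation": (0.72, 0.18, 0.16),
    "slough": (0.86, 0.78, 0.35),
    "necrotic": (0.10, 0.07, 0.05),
}
_DEFAULT_NOISE_SD = 0.03


@dataclass(frozen=True)
class SceneParams:
    """Geometry, appearance and randomness controls for one scene.

    ``wound_radius_range`` is in pixels; None derives (0.15, 0.30) of the
    short image side.  ``irregularity`` scales the radial sinusoidal
    perturbation of the wound boundary; ``illumination`` is the relative
    amplitude of a linear shading gradient across the frame.
    """

    height: int = 128
    width: int = 128
    seed: int = 0
    class_colors: dict = field(default_factory=lambda: dict(_DEFAULT_COLORS))
    noise_sd: float = _DEFAULT_NOISE_SD
    wound_radius_range: tuple[float, float] | None = None
    irregularity: float = 0.15
    illumination: float = 0.10
    include_slough: bool = True
    include_necrotic: bool = True

    def __post_init__(self):
        if self.height < 32 or self.width < 32:
            raise DomainError("scene must be at least 32x32")
        for name, c in self.class_colors.items():
            if any(not (0.0 <= v <= 1.0) for v in c):
                raise DomainError(f"color mean for {name!r} outside [0, 1]")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be nonnegative")
        if self.irregularity < 0:
            raise DomainError("irregularity must be nonnegative")
        if not (0.0 <= self.illumination <= 1.0):
            raise DomainError("illumination must lie in [0, 1]")

    def radius_range(self) -> tuple[float, float]:
        if self.wound_radius_range is not None:
            lo, hi = self.wound_radius_range
            if not (0 < lo <= hi):
                raise DomainError("wound radius range must satisfy 0 < lo <= hi")
            return float(lo), float(hi)
        side = min(self.height, self.width)
        return 0.15 * side, 0.30 * side

    def enabled_classes(self) -> list[str]:
        names = ["background", "intact_skin", "granulation"]
        if self.include_slough:
            names.append("slough")
        if self.include_necrotic:
            names.append("necrotic")
        return names


@dataclass(frozen=True)
class SyntheticScene:
    image: RasterImage
    truth: LabelMap
    params: SceneParams


def _class_ids(palette: TissuePalette) -> dict[str, int]:
    return {c.name: c.id for c in palette.classes}


def generate_scene(
    params: SceneParams | None = None, palette: TissuePalette | None = None
) -> SyntheticScene:
    """Draw one scene; bit-identical for identical params."""
    p = params or SceneParams()
    palette = palette or TissuePalette.default()
    ids = _class_ids(palette)
    h, w = p.height, p.width
    rng = np.random.default_rng(p.seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    # skin ellipse covering >= 40% of the frame, jittered around the center
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    ry = 0.40 * h
    rx = 0.44 * w
    skin = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    # wound bed: closed curve r(theta) = R * (1 + irregularity * sum of
    # low-order sinusoids with seeded phases), intersected with the skin
    r_lo, r_hi = p.radius_range()
    big_r = rng.uniform(r_lo, r_hi)
    wy = cy + rng.uniform(-0.1, 0.1) * big_r
    wx = cx + rng.uniform(-0.1, 0.1) * big_r
    harmonics = np.arange(2, 6)
    amps = rng.uniform(0.3, 1.0, size=harmonics.size) / harmonics
    amps *= p.irregularity / max(amps.sum(), 1e-12)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=harmonics.size)
    theta = np.arctan2(yy - wy, xx - wx)
    factor = np.ones_like(theta)
    for hharm, a, ph in zip(harmonics, amps, phases):
        factor += a * np.sin(hharm * theta + ph)
    boundary = big_r * np.clip(factor, 0.2, None)
    rr = np.sqrt((yy - wy) ** 2 + (xx - wx) ** 2)
    wound = (rr <= boundary) & skin

    truth = np.full((h, w), ids["background"], dtype=np.int32)
    truth[skin] = ids["intact_skin"]
    truth[wound] = ids["granulation"]

    def paint_blobs(class_name: str, n_blobs: int, rad_frac: float) -> None:
        mask = np.zeros((h, w), dtype=bool)
        for _ in range(n_blobs):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            dist = rng.uniform(0.0, 0.55) * big_r
            by, bx = wy + dist * math.sin(ang), wx + dist * math.cos(ang)
            br = max(2.0, rng.uniform(0.6, 1.0) * rad_frac * big_r)
            mask |= (yy - by) ** 2 + (xx - bx) ** 2 <= br**2
        mask &= wound
        if not mask.any():
            # degenerate rasterization: guarantee the class exists with a
            # small patch inside the wound bed
            rows, cols = np.nonzero(wound)
            mask[rows[0] : rows[0] + 2, cols[0] : cols[0] + 2] = True
            mask &= wound
        truth[mask] = ids[class_name]

    if not wound.any():  # wound entirely off-skin cannot happen by
        raise DomainError("degenerate geometry: wound region empty")  # construction
    if p.include_slough:
        paint_blobs("slough", n_blobs=3, rad_frac=0.30)
    if p.include_necrotic:
        paint_blobs("necrotic", n_blobs=2, rad_frac=0.20)
    # blobs may tile the bed; keep at least a patch of granulation
    if not (truth == ids["granulation"]).any():
        rows, cols = np.nonzero(wound)
        truth[rows[: max(4, len(rows) // 50)], cols[: max(4, len(cols) // 50)]] = ids[
            "granulation"
        ]

    # per-pixel color: class mean + Gaussian noise, then linear shading
    image = np.empty((h, w, 3), dtype=np.float64)
    for name in p.enabled_classes():
        image[truth == ids[name]] = p.class_colors[name]
    image += rng.normal(0.0, p.noise_sd, size=image.shape)
    if p.illumination > 0:
        ang = rng.uniform(0.0, 2.0 * math.pi)
        t = (
            (yy - h / 2) * math.sin(ang) + (xx - w / 2) * math.cos(ang)
        ) / (0.5 * math.hypot(h, w))
        image *= (1.0 + p.illumination * t)[..., None]
    image = np.clip(image, 0.0, 1.0)

    return SyntheticScene(
        RasterImage(image, copy=False), LabelMap(truth, copy=False), p
    )


def oracle_select(proposal: SuperpixelMap, truth: LabelMap) -> LabelMap:
    """Assign each segment its majority truth class (ties: smallest id)."""
    if (proposal.height, proposal.width) != truth.shape:
        raise DomainError(
            f"dimension mismatch: proposal {(proposal.height, proposal.width)} "
            f"vs truth {truth.shape}"
        )
    seg = proposal.labels.ravel()
    cls = truth.labels.ravel()
    n_seg = proposal.n_segments
    n_cls = int(cls.max()) + 1
    votes = np.zeros((n_seg, n_cls), dtype=np.int64)
    np.add.at(votes, (seg, cls), 1)
    majority = votes.argmax(axis=1).astype(np.int32)  # argmax ties -> lowest id
    return LabelMap(majority[seg].reshape(truth.shape), copy=False)


def achievable_metrics(
    scene: SyntheticScene,
    algorithm: str,
    params=None,
    palette: TissuePalette | None = None,
) -> list[ClassMetrics]:
    """Propose on the scene, select segments perfectly, score against truth.

    Measures how closely a superpixel-selection workflow can approximate
    pixel-level labeling for the given algorithm and parameters.
    """
    palette = palette or TissuePalette.default()
    if algorithm not in _SEGMENTERS:
        raise DomainError(f"unknown algorithm {algorithm!r}")
    if params is None:
        params = _PARAM_TYPES[algorithm]()
    proposal = _SEGMENTERS[algorithm](scene.image, params)
    pred = oracle_select(proposal, scene.truth)
    cm = confusion_matrix(pred, scene.truth, palette, ignore_unlabeled=False)
    return class_metrics(cm)


def fixture_scene_params() -> list[SceneParams]:
    """Six pinned-seed study scenes: with/without necrotic tissue, low/high
    noise, low/high boundary irregularity (all 128x128)."""
    base = SceneParams()
    return [
        replace(base, seed=101),
        replace(base, seed=102, include_necrotic=False),
        replace(base, seed=103, noise_sd=0.01),
        replace(base, seed=104, noise_sd=0.06),
        replace(base, seed=105, irregularity=0.05),
        replace(base, seed=106, irregularity=0.30, include_necrotic=False),
    ]
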