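"""Labeling sessions: proposals, segment selection, manual corrections,
session-script replay and paletted label output.

The interactive two-stage workflow — propose partitions of the working
image, then pick segments into tissue classes, touching up with a brush or
a flood-fill wand — is driven here by deterministic session scripts rather
than mouse events, so a labeling run is fully reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .clustering import KMeansParams, kmeans_segment
from .errors import (
    CompletenessError,
    ConfigurationError,
    DomainError,
    ScriptError,
)
from .imagecore import RasterImage, Rect, crop, gamma_correct, save_image
from .superpixels import (
    FelzParams,
    QuickshiftParams,
    SlicParams,
    SuperpixelMap,
    felzenszwalb_segment,
    quickshift_segment,
    slic_segment,
)

__all__ = [
    "TissueClass",
    "TissuePalette",
    "LabelMap",
    "Session",
    "SessionScript",
    "new_session",
    "propose",
    "select_segment",
    "brush",
    "magic_wand",
    "run_script",
    "save_pair",
    "load_label_map",
    "load_palette",
]

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

# Display color for palette index 0 ("unlabeled") in label PNGs; magenta is
# outside every built-in tissue palette.
_UNLABELED_COLOR = (255, 0, 255)


# ---------------------------------------------------------------------------
# palette

@dataclass(frozen=True)
class TissueClass:
    id: int
    name: str
    color: tuple[int, int, int]


class TissuePalette:
    """Ordered tissue classes with ids 1..C; id 0 is reserved for unlabeled."""

    def __init__(self, classes):
        classes = [TissueClass(int(c.id), str(c.name), tuple(c.color)) for c in classes]
        if not classes:
            raise ConfigurationError("palette must contain at least one class")
        ids = [c.id for c in classes]
        if ids != list(range(1, len(classes) + 1)):
            raise ConfigurationError(f"class ids must be consecutive 1..C, got {ids}")
        names = [c.name for c in classes]
        colors = [c.color for c in classes]
        if len(set(names)) != len(names) or len(set(colors)) != len(colors):
            raise ConfigurationError("class names and colors must be unique")
        for c in colors:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ConfigurationError(f"invalid RGB color {c}")
        self.classes = classes
        self._by_name = {c.name: c for c in classes}
        self._by_id = {c.id: c for c in classes}

    def __len__(self) -> int:
        return len(self.classes)

    def __eq__(self, other) -> bool:
        return isinstance(other, TissuePalette) and self.classes == other.classes

    @property
    def ids(self) -> list[int]:
        return [c.id for c in self.classes]

    def resolve(self, class_ref) -> int:
        """Map a class id or name to its id, validating membership."""
        if isinstance(class_ref, str):
            if class_ref not in self._by_name:
                raise DomainError(f"unknown tissue class {class_ref!r}")
            return self._by_name[class_ref].id
        cid = int(class_ref)
        if cid not in self._by_id:
            raise DomainError(f"class id {cid} not in palette")
        return cid

    def name_of(self, class_id: int) -> str:
        return self._by_id[int(class_id)].name

    def color_of(self, class_id: int) -> tuple[int, int, int]:
        return self._by_id[int(class_id)].color

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": [
                    {"id": c.id, "name": c.name, "color": list(c.color)}
                    for c in self.classes
                ]
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TissuePalette":
        payload = json.loads(text)
        return cls(
            [
                TissueClass(e["id"], e["name"], tuple(e["color"]))
                for e in payload["classes"]
            ]
        )

    @classmethod
    def default(cls) -> "TissuePalette":
        """Five wound-tissue classes with the labeled-output legend colors:
        background blue, intact skin green, granulation red, slough yellow,
        necrotic black."""
        return cls(
            [
                TissueClass(1, "background", (0, 0, 255)),
                TissueClass(2, "intact_skin", (0, 255, 0)),
                TissueClass(3, "granulation", (255, 0, 0)),
                TissueClass(4, "slough", (255, 255, 0)),
                TissueClass(5, "necrotic", (0, 0, 0)),
            ]
        )

    @classmethod
    def editor_preset(cls) -> "TissuePalette":
        """Alternative legend used by pixel-editor workflows: intact skin
        blue, granulation red, slough yellow, necrotic black; background is
        shown gray."""
        return cls(
            [
                TissueClass(1, "background", (128, 128, 128)),
                TissueClass(2, "intact_skin", (0, 0, 255)),
                TissueClass(3, "granulation", (255, 0, 0)),
                TissueClass(4, "slough", (255, 255, 0)),
                TissueClass(5, "necrotic", (0, 0, 0)),
            ]
        )


# ---------------------------------------------------------------------------
# label map

class LabelMap:
    """Per-pixel tissue-class assignment; 0 means unlabeled."""

    __slots__ = ("labels",)

    def __init__(self, labels: np.ndarray, copy: bool = True):
        arr = np.array(labels, dtype=np.int32, copy=copy)
        if arr.ndim != 2 or arr.size == 0:
            raise DomainError(f"expected a nonempty HxW label array, got {arr.shape}")
        if arr.min() < 0:
            raise DomainError("class ids must be nonnegative")
        self.labels = arr

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def unlabeled_count(self) -> int:
        return int((self.labels == 0).sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelMap) and np.array_equal(self.labels, other.labels)

    @classmethod
    def empty(cls, height: int, width: int) -> "LabelMap":
        return cls(np.zeros((height, width), dtype=np.int32), copy=False)


# ---------------------------------------------------------------------------
# session

_PARAM_TYPES = {
    "felzenszwalb": FelzParams,
    "slic": SlicParams,
    "quickshift": QuickshiftParams,
    "kmeans": KMeansParams,
}
_SEGMENTERS = {
    "felzenszwalb": felzenszwalb_segment,
    "slic": slic_segment,
    "quickshift": quickshift_segment,
    "kmeans": kmeans_segment,
}


class Session:
    """Mutable labeling state: working image, mask, palette, active region
    and the ordered list of proposals produced so far."""

    def __init__(self, image: RasterImage, palette: TissuePalette):
        self.image = image.copy()
        self.palette = palette
        self.mask = LabelMap.empty(image.height, image.width)
        self.active_region = Rect.full(image.height, image.width)
        self.proposals: list[SuperpixelMap] = []
        self._cache: dict = {}

    def set_gamma(self, gamma: float) -> None:
        """Apply gamma to the working image; later proposals see the change."""
        self.image = gamma_correct(self.image, gamma)
        self._cache.clear()

    def set_region(self, region: Rect | None) -> None:
        if region is None:
            region = Rect.full(self.image.height, self.image.width)
        region.validate(self.image.height, self.image.width)
        self.active_region = region


def new_session(img: RasterImage, palette: TissuePalette | None = None) -> Session:
    return Session(img, palette or TissuePalette.default())


def propose(session: Session, algorithm: str, params=None) -> SuperpixelMap:
    """Segment the active region with the named algorithm and store the result.

    Identical (algorithm, params, region) calls on an unchanged working
    image return the cached identical proposal.
    """
    if algorithm not in _SEGMENTERS:
        raise DomainError(
            f"unknown algorithm {algorithm!r}; expected one of {sorted(_SEGMENTERS)}"
        )
    if params is None:
        params = _PARAM_TYPES[algorithm]()
    if not isinstance(params, _PARAM_TYPES[algorithm]):
        raise DomainError(
            f"{algorithm} expects {_PARAM_TYPES[algorithm].__name__}, "
            f"got {type(params).__name__}"
        )
    region = session.active_region
    key = (algorithm, params, region)
    if key in session._cache:
        result = session._cache[key]
    else:
        sub = crop(session.image, region)
        labels = _SEGMENTERS[algorithm](sub, params).labels
        result = SuperpixelMap(labels, region=region, copy=False)
        session._cache[key] = result
    session.proposals.append(result)
    return result


def select_segment(
    session: Session, proposal: SuperpixelMap, segment_id: int, class_ref
) -> int:
    """Write one proposal segment into the mask; returns pixels written."""
    cid = session.palette.resolve(class_ref)
    mask = proposal.segment_mask(int(segment_id))
    region = proposal.region or Rect.full(proposal.height, proposal.width)
    region.validate(session.image.height, session.image.width)
    if region.shape != (proposal.height, proposal.width):
        raise DomainError("proposal dimensions do not match its region")
    view = session.mask.labels[region.top : region.bottom, region.left : region.right]
    view[mask] = cid
    return int(mask.sum())


def brush(session: Session, center: tuple[int, int], radius: float, class_ref) -> int:
    """Paint a Euclidean disc of the given radius, clipped to the image."""
    cid = session.palette.resolve(class_ref)
    row, col = int(center[0]), int(center[1])
    h, w = session.mask.shape
    if not (0 <= row < h and 0 <= col < w):
        raise DomainError(f"brush center {center} outside {h}x{w} image")
    if radius < 0:
        raise DomainError("radius must be nonnegative")
    r = int(math.floor(radius))
    r0, r1 = max(0, row - r), min(h, row + r + 1)
    c0, c1 = max(0, col - r), min(w, col + r + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    disc = (yy - row) ** 2 + (xx - col) ** 2 <= radius**2
    session.mask.labels[r0:r1, c0:c1][disc] = cid
    return int(disc.sum())


def magic_wand(
    session: Session, seed: tuple[int, int], tolerance: float, class_ref
) -> int:
    """Flood fill from the seed over 4-connectivity.

    A pixel is admitted iff its Euclidean RGB distance to the *seed pixel*
    is at most ``tolerance``; the admitted set is the connected component
    of admissible pixels containing the seed.
    """
    cid = session.palette.resolve(class_ref)
    row, col = int(seed[0]), int(seed[1])
    h, w = session.mask.shape
    if not (0 <= row < h and 0 <= col < w):
        raise DomainError(f"wand seed {seed} outside {h}x{w} image")
    if tolerance < 0:
        raise DomainError("tolerance must be nonnegative")
    seed_color = session.image.data[row, col]
    dist = np.sqrt(((session.image.data - seed_color) ** 2).sum(axis=2))
    admissible = dist <= tolerance
    comp, _ = ndimage.label(admissible, structure=_FOUR_CONN)
    selected = comp == comp[row, col]
    session.mask.labels[selected] = cid
    return int(selected.sum())


# ---------------------------------------------------------------------------
# paletted-PNG output

def save_pair(session: Session, stem, allow_unlabeled: bool = False):
    """Write ``<stem>.png`` (working image), ``<stem>_label.png`` (paletted
    PNG, palette index = class id, 0 = unlabeled) and
    ``<stem>_palette.json``.  Returns the two image paths."""
    if not allow_unlabeled:
        n0 = session.mask.unlabeled_count()
        if n0 > 0:
            raise CompletenessError(n0)
    stem = Path(stem)
    img_path = stem.with_suffix(".png")
    label_path = stem.parent / f"{stem.name}_label.png"
    palette_path = stem.parent / f"{stem.name}_palette.json"
    save_image(session.image, img_path)
    _write_label_png(session.mask, session.palette, label_path)
    palette_path.write_text(session.palette.to_json())
    return img_path, label_path


def _write_label_png(mask: LabelMap, palette: TissuePalette, path) -> None:
    if mask.labels.max() > 255:
        raise DomainError("paletted PNG supports at most 255 classes")
    im = Image.fromarray(mask.labels.astype(np.uint8), mode="P")
    flat = list(_UNLABELED_COLOR)
    for c in palette.classes:
        flat.extend(c.color)
    flat.extend([0] * (768 - len(flat)))
    im.putpalette(flat)
    im.save(Path(path), format="PNG")


def load_label_map(path) -> LabelMap:
    """Read a paletted label PNG back into a LabelMap (palette index = id)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such label file: {p}")
    with Image.open(p) as im:
        if im.mode != "P":
            raise DomainError(f"{p} is not a paletted PNG")
        arr = np.asarray(im, dtype=np.int32)
    return LabelMap(arr, copy=False)


def load_palette(path) -> TissuePalette:
    return TissuePalette.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# session scripts

class SessionScript:
    """An ordered list of JSON action objects replayable on any image.

    Supported ops: ``set_gamma``, ``set_region``, ``propose``, ``select``,
    ``brush``, ``wand``, ``save``.  ``select`` refers to proposals by the
    zero-based order in which ``propose`` actions ran.
    """

    def __init__(self, actions):
        self.actions = [dict(a) for a in actions]

    @classmethod
    def from_json(cls, text: str) -> "SessionScript":
        payload = json.loads(text)
        if not isinstance(payload, list):
            raise DomainError("session script must be a JSON list of actions")
        return cls(payload)

    @classmethod
    def load(cls, path) -> "SessionScript":
        return cls.from_json(Path(path).read_text())

    def to_json(self) -> str:
        return json.dumps(self.actions, indent=2)

    def __len__(self) -> int:
        return len(self.actions)


def _apply_action(session: Session, action: dict, saved: list) -> None:
    op = action.get("op")
    if op == "set_gamma":
        session.set_gamma(float(action["gamma"]))
    elif op == "set_region":
        if action.get("full", False):
            session.set_region(None)
        else:
            session.set_region(
                Rect(
                    int(action["top"]),
                    int(action["left"]),
                    int(action["bottom"]),
                    int(action["right"]),
                )
            )
    elif op == "propose":
        algo = action["algorithm"]
        if algo not in _PARAM_TYPES:
            raise DomainError(f"unknown algorithm {algo!r}")
        fields = {
            k: v for k, v in action.items() if k not in ("op", "algorithm")
        }
        propose(session, algo, _PARAM_TYPES[algo](**fields))
    elif op == "select":
        idx = int(action["proposal"])
        if not (0 <= idx < len(session.proposals)):
            raise DomainError(f"proposal index {idx} out of range")
        select_segment(
            session, session.proposals[idx], int(action["segment"]), action["class"]
        )
    elif op == "brush":
        brush(
            session,
            (action["row"], action["col"]),
            float(action["radius"]),
            action["class"],
        )
    elif op == "wand":
        magic_wand(
            session,
            (action["row"], action["col"]),
            float(action["tolerance"]),
            action["class"],
        )
    elif op == "save":
        saved.extend(
            save_pair(session, action["stem"], bool(action.get("allow_unlabeled", False)))
        )
    else:
        raise DomainError(f"unknown op {op!r}")


def run_script(
    img: RasterImage,
    script: SessionScript,
    palette: TissuePalette | None = None,
):
    """Replay a session script on a fresh session; returns (mask, saved paths).

    The first invalid action aborts with a ScriptError carrying its index.
    """
    session = new_session(img, palette)
    saved: list = []
    for i, action in enumerate(script.actions):
        try:
            _apply_action(session, action, saved)
        except Exception as exc:
            raise ScriptError(i, str(exc)) from exc
    return session.mask, saved
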