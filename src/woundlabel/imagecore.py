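"""Raster image container, file I/O and basic image operations.

The working pixel domain is continuous: an RGB image holds float channel
values in [0, 1] and 8-bit quantization happens only when a file is read or
written.  Color conversion to CIELAB uses the exact piecewise sRGB transfer
function and the D65 white point.  Rectangular regions are half-open,
0-based and row-major throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

from .errors import DomainError, FormatError

__all__ = [
    "RasterImage",
    "LabImage",
    "Rect",
    "load_image",
    "save_image",
    "to_lab",
    "gamma_correct",
    "gaussian_smooth",
    "crop",
]


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class Rect:
    """Half-open rectangle [top, bottom) x [left, right), 0-based."""

    top: int
    left: int
    bottom: int
    right: int

    def validate(self, height: int, width: int) -> None:
        if not (0 <= self.top < self.bottom <= height):
            raise DomainError(
                f"row range [{self.top}, {self.bottom}) invalid for height {height}"
            )
        if not (0 <= self.left < self.right <= width):
            raise DomainError(
                f"column range [{self.left}, {self.right}) invalid for width {width}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.bottom - self.top, self.right - self.left)

    @classmethod
    def full(cls, height: int, width: int) -> "Rect":
        return cls(0, 0, height, width)


class RasterImage:
    """An H x W x 3 RGB raster with float channel values in [0, 1]."""

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray, copy: bool = True):
        arr = np.array(data, dtype=np.float64, copy=copy)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise DomainError(f"expected an HxWx3 array, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DomainError("image must be at least 1x1")
        if not np.isfinite(arr).all():
            raise DomainError("image contains non-finite values")
        if arr.min() < 0.0 or arr.max() > 1.0:
            raise DomainError("channel values must lie in [0, 1]")
        self.data = arr

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def copy(self) -> "RasterImage":
        return RasterImage(self.data, copy=True)

    def __eq__(self, other) -> bool:
        return isinstance(other, RasterImage) and np.array_equal(self.data, other.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RasterImage({self.height}x{self.width})"


class LabImage:
    """An H x W x 3 CIELAB raster; L in [0, 100], a/b unbounded."""

    __slots__ = ("data",)

    def __init__(self, data: np.ndarray, copy: bool = True):
        arr = np.array(data, dtype=np.float64, copy=copy)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise DomainError(f"expected an HxWx3 array, got shape {arr.shape}")
        self.data = arr

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


# ---------------------------------------------------------------------------
# file I/O (8-bit sRGB PNG/JPEG)

def load_image(path) -> RasterImage:
    """Read a PNG or JPEG file into a RasterImage.

    Channel bytes are scaled to [0, 1] by division by 255.  Alpha channels
    are dropped; grayscale images are replicated across the three channels.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"no such image file: {p}")
    try:
        with Image.open(p) as im:
            im = im.convert("RGB")
            arr = np.asarray(im, dtype=np.float64) / 255.0
    except UnidentifiedImageError as exc:
        raise FormatError(f"cannot decode {p} as PNG or JPEG") from exc
    return RasterImage(arr, copy=False)


def save_image(img: RasterImage, path) -> None:
    """Write an 8-bit RGB PNG; channel value c is stored as round(c*255)."""
    # np.round is round-half-even; the file contract is round-half-up.
    q = np.floor(img.data * 255.0 + 0.5).astype(np.uint8)
    Image.fromarray(q, mode="RGB").save(Path(path), format="PNG")


# ---------------------------------------------------------------------------
# sRGB -> CIELAB (D65)

_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_D65_WHITE = np.array([0.95047, 1.0, 1.08883])
_LAB_DELTA = 6.0 / 29.0


def _srgb_linearize(v: np.ndarray) -> np.ndarray:
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(
        t > _LAB_DELTA**3,
        np.cbrt(t),
        t / (3.0 * _LAB_DELTA**2) + 4.0 / 29.0,
    )


def to_lab(img: RasterImage) -> LabImage:
    """Convert sRGB to CIELAB (exact piecewise transfer function, D65)."""
    lin = _srgb_linearize(img.data)
    xyz = lin @ _SRGB_TO_XYZ.T
    f = _lab_f(xyz / _D65_WHITE)
    lab = np.empty_like(xyz)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return LabImage(lab, copy=False)


# ---------------------------------------------------------------------------
# pixel operations

def gamma_correct(img: RasterImage, gamma: float) -> RasterImage:
    """Raise every channel value to the power ``gamma`` (v -> v**gamma).

    gamma < 1 brightens, gamma > 1 darkens; 0 and 1 are fixed points.
    """
    if not (gamma > 0):
        raise DomainError(f"gamma must be positive, got {gamma}")
    return RasterImage(np.power(img.data, gamma), copy=False)


def gaussian_smooth(img: RasterImage, sigma: float) -> RasterImage:
    """Per-channel Gaussian smoothing with reflective boundary handling."""
    if sigma < 0:
        raise DomainError(f"sigma must be nonnegative, got {sigma}")
    if sigma == 0:
        return img.copy()
    out = ndimage.gaussian_filter(img.data, sigma=(sigma, sigma, 0), mode="reflect")
    return RasterImage(np.clip(out, 0.0, 1.0), copy=False)


def crop(img: RasterImage, region: Rect) -> RasterImage:
    """Extract the sub-image covered by ``region`` (no resampling)."""
    region.validate(img.height, img.width)
    sub = img.data[region.top : region.bottom, region.left : region.right]
    return RasterImage(sub, copy=True)
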