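"""Shared coordinate conventions, masks, boxes and physical units.

Everything downstream (prompt generation, segmentation, evaluation,
capillarization measurements) is built on the primitives defined here.

Conventions
-----------
* Pixel coordinates are 0-based. ``x`` indexes columns, ``y`` indexes rows.
* Bounding boxes are axis-aligned and half-open:
  ``[x_min, x_max) x [y_min, y_max)``, so ``area == width * height`` exactly
  and a box circumscribing pixels in columns 2..5 has ``x_min=2, x_max=6``.
* Point-in-box membership is inclusive at the lower edge and exclusive at
  the upper edge; boundary ties are therefore resolved deterministically.
* A box centroid is the geometric centre of the box, not the mask's centre
  of mass: at inference time only detections (boxes) exist, no masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple, Optional, Tuple

import numpy as np


class ClassLabel(str, Enum):
    """The two structure classes: cardiomyocyte profiles and capillaries."""

    CM = "CM"
    CAP = "CAP"


class Point2D(NamedTuple):
    x: float
    y: float


@dataclass(frozen=True)
class ImageMeta:
    """Acquisition geometry of one field of view.

    Default values match confocal acquisition of basement-membrane
    immunostains: 512 x 512 pixels, 16-bit, over a 42.5 um x 42.5 um FOV.
    """

    width_px: int = 512
    height_px: int = 512
    fov_um: Tuple[float, float] = (42.5, 42.5)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.fov_um[0] <= 0 or self.fov_um[1] <= 0:
            raise ValueError("FOV extents must be positive")

    @property
    def pixel_size_um(self) -> Tuple[float, float]:
        """(x, y) pixel pitch in micrometres."""
        return (self.fov_um[0] / self.width_px, self.fov_um[1] / self.height_px)

    @property
    def pixel_area_um2(self) -> float:
        px, py = self.pixel_size_um
        return px * py

    @property
    def fov_area_um2(self) -> float:
        return self.fov_um[0] * self.fov_um[1]

    @property
    def shape(self) -> Tuple[int, int]:
        """Raster shape as (rows, cols)."""
        return (self.height_px, self.width_px)


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box in pixel units."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    def as_xywh(self) -> Tuple[float, float, float, float]:
        """COCO-style [x, y, w, h]."""
        return (self.x_min, self.y_min, self.width, self.height)

    @staticmethod
    def from_xywh(x: float, y: float, w: float, h: float) -> "BoundingBox":
        return BoundingBox(x, y, x + w, y + h)


@dataclass
class InstanceMask:
    """One labelled instance: a binary raster plus a class label.

    An empty raster is permitted only to signal a failed prediction; valid
    instances have at least one foreground pixel.
    """

    raster: np.ndarray
    label: ClassLabel
    score: Optional[float] = None

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("mask raster must be 2-D")
        self.label = ClassLabel(self.label)

    @property
    def is_empty(self) -> bool:
        return not bool(self.raster.any())

    @property
    def pixel_count(self) -> int:
        return int(self.raster.sum())


class EmptyMaskError(ValueError):
    """Raised when an operation requires at least one foreground pixel."""


def bbox_from_mask(mask: InstanceMask | np.ndarray) -> BoundingBox:
    """Tightest axis-aligned half-open box containing every foreground pixel.

    Raises
    ------
    EmptyMaskError
        If the mask has no foreground pixel (never returns a degenerate box).
    """
    raster = mask.raster if isinstance(mask, InstanceMask) else np.asarray(mask, bool)
    rows = np.flatnonzero(raster.any(axis=1))
    cols = np.flatnonzero(raster.any(axis=0))
    if rows.size == 0:
        raise EmptyMaskError("cannot circumscribe an empty mask")
    return BoundingBox(
        x_min=float(cols[0]),
        y_min=float(rows[0]),
        x_max=float(cols[-1] + 1),
        y_max=float(rows[-1] + 1),
    )


def bbox_centroid(box: BoundingBox) -> Point2D:
    """Geometric centre of a box (the prompt anchor c_i)."""
    return Point2D((box.x_min + box.x_max) / 2.0, (box.y_min + box.y_max) / 2.0)


def point_in_box(p: Point2D | Tuple[float, float], box: BoundingBox) -> bool:
    """Half-open membership: lower edges inclusive, upper edges exclusive."""
    x, y = p
    return box.x_min <= x < box.x_max and box.y_min <= y < box.y_max


def mask_iou(m_p: InstanceMask, m_gt: InstanceMask) -> float:
    """Intersection over union of two foreground rasters, in [0, 1]."""
    a, b = m_p.raster, m_gt.raster
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        raise EmptyMaskError("IoU undefined: both masks empty")
    inter = int(np.logical_and(a, b).sum())
    return inter / union


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """IoU of two boxes (used for scene statistics on annotations)."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def box_contains_box(outer: BoundingBox, inner: BoundingBox) -> bool:
    return (
        outer.x_min <= inner.x_min
        and outer.y_min <= inner.y_min
        and outer.x_max >= inner.x_max
        and outer.y_max >= inner.y_max
    )


def mask_area_um2(mask: InstanceMask, meta: ImageMeta) -> float:
    """Foreground area in square micrometres under the given pixel pitch."""
    if mask.raster.shape != meta.shape:
        raise ValueError(
            f"mask shape {mask.raster.shape} does not match meta {meta.shape}"
        )
    return mask.pixel_count * meta.pixel_area_um2
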