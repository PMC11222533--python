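"""Dataset preparation: preprocessing, splits, augmentation, weak annotation.

Mirrors the training workflow: raw 16-bit confocal frames are Wiener
filtered (3x3) and contrast enhanced; the image set is split 70/30 into
train+val/test with 10% of train+val held out for validation (round half
up reproduces the canonical 107 -> 67/8/32 partition); training images are
augmented by the three fixed rotations (90 cw, 90 ccw, 180) and by mosaic
composition of four downscaled images into quadrants; weak annotations are
boxes circumscribing the manually segmented masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.signal import wiener
from skimage.measure import block_reduce

from .geometry import (
    BoundingBox,
    ClassLabel,
    ImageMeta,
    InstanceMask,
    bbox_from_mask,
)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    raw: np.ndarray,
    clip_percentiles: Tuple[float, float] = (0.35, 99.65),
) -> np.ndarray:
    """3x3 Wiener filter followed by a linear percentile contrast stretch.

    Output is uint16 over the full dynamic range. Deterministic. A
    zero-variance (constant) input maps to all zeros: the Wiener filter is
    the identity on it and the degenerate stretch has nothing to scale.
    """
    if raw.ndim != 2:
        raise ValueError("preprocess expects a 2-D grayscale raster")
    img = np.asarray(raw, dtype=np.float64)
    if np.ptp(img) == 0:
        return np.zeros_like(img, dtype=np.uint16)
    with np.errstate(divide="ignore", invalid="ignore"):
        smoothed = wiener(img, (3, 3))
    smoothed = np.nan_to_num(smoothed, nan=0.0)
    lo, hi = np.percentile(smoothed, clip_percentiles)
    if hi <= lo:
        return np.zeros_like(img, dtype=np.uint16)
    stretched = np.clip((smoothed - lo) / (hi - lo), 0.0, 1.0)
    return (stretched * 65535.0 + 0.5).astype(np.uint16)


def structure_coverage(masks: Sequence[InstanceMask], meta: ImageMeta) -> float:
    """Fraction of the FOV covered by the union of annotated structures."""
    if not masks:
        return 0.0
    union = np.zeros(meta.shape, dtype=bool)
    for m in masks:
        if m.raster.shape != meta.shape:
            raise ValueError("mask does not match image meta")
        union |= m.raster
    return float(union.sum()) / (meta.width_px * meta.height_px)


def passes_roi_criterion(
    masks: Sequence[InstanceMask], meta: ImageMeta, min_coverage: float = 0.80
) -> bool:
    """ROI admission: at least 80% of the FOV must contain annotated
    myocardial structures."""
    return structure_coverage(masks, meta) >= min_coverage


# ---------------------------------------------------------------------------
# Dataset split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.30
    val_fraction_of_trainval: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.val_fraction_of_trainval):
            if not (0.0 < f < 1.0):
                raise ValueError("split fractions must lie in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    n_items: int, spec: SplitSpec
) -> Tuple[List[int], List[int], List[int]]:
    """Seeded shuffle then partition into (train, val, test) index lists.

    test = round-half-up(test_fraction * n); val = round-half-up
    (val_fraction * (n - test)); train = remainder. Every part must be
    non-empty.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to split")
    n_test = _round_half_up(spec.test_fraction * n_items)
    n_val = _round_half_up(spec.val_fraction_of_trainval * (n_items - n_test))
    n_train = n_items - n_test - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"degenerate split for n={n_items}: "
            f"({n_train}, {n_val}, {n_test})"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_items)
    test = sorted(int(i) for i in perm[:n_test])
    val = sorted(int(i) for i in perm[n_test : n_test + n_val])
    train = sorted(int(i) for i in perm[n_test + n_val :])
    return train, val, test


def split_manifest(n_items: int, spec: SplitSpec) -> Dict:
    """JSON-ready manifest recording the seed alongside the index lists."""
    train, val, test = split_dataset(n_items, spec)
    return {
        "n_items": n_items,
        "seed": spec.seed,
        "test_fraction": spec.test_fraction,
        "val_fraction_of_trainval": spec.val_fraction_of_trainval,
        "train": train,
        "val": val,
        "test": test,
    }


# ---------------------------------------------------------------------------
# Rotation augmentation
# ---------------------------------------------------------------------------

ROTATIONS = ("cw90", "ccw90", "rot180")


@dataclass(frozen=True)
class AugmentationConfig:
    rotations: Tuple[str, ...] = ROTATIONS
    mosaic: bool = True
    target_total: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        bad = set(self.rotations) - set(ROTATIONS)
        if bad:
            raise ValueError(f"unsupported rotations: {sorted(bad)}")


def _rot_image(image: np.ndarray, direction: str) -> np.ndarray:
    if direction == "cw90":
        return np.rot90(image, k=-1)
    if direction == "ccw90":
        return np.rot90(image, k=1)
    if direction == "rot180":
        return np.rot90(image, k=2)
    raise ValueError(f"unknown rotation {direction!r}")


def rotate_box(box: BoundingBox, direction: str, size: int) -> BoundingBox:
    """Transform a box under a rotation of a size x size frame."""
    x0, y0, x1, y1 = box.as_tuple()
    if direction == "cw90":
        return BoundingBox(size - y1, x0, size - y0, x1)
    if direction == "ccw90":
        return BoundingBox(y0, size - x1, y1, size - x0)
    if direction == "rot180":
        return BoundingBox(size - x1, size - y1, size - x0, size - y0)
    raise ValueError(f"unknown rotation {direction!r}")


def rotate_augment(
    image: np.ndarray, masks: Sequence[InstanceMask]
) -> List[Tuple[str, np.ndarray, List[InstanceMask]]]:
    """Emit the three fixed rotated copies of (image, masks).

    90-degree rotations require a square raster.
    """
    if image.shape[0] != image.shape[1]:
        raise ValueError("90-degree rotations require a square raster")
    out = []
    for direction in ROTATIONS:
        rimg = _rot_image(image, direction)
        rmasks = [
            InstanceMask(_rot_image(m.raster, direction), m.label, m.score)
            for m in masks
        ]
        out.append((direction, rimg, rmasks))
    return out


# ---------------------------------------------------------------------------
# Mosaic augmentation
# ---------------------------------------------------------------------------

def downscale_box(box: BoundingBox) -> BoundingBox:
    """Halve a box with the same floor/ceil rule the mask downscaling uses,
    so bbox(downscale(mask)) == downscale_box(bbox(mask)) exactly."""
    return BoundingBox(
        math.floor(box.x_min / 2),
        math.floor(box.y_min / 2),
        math.ceil(box.x_max / 2),
        math.ceil(box.y_max / 2),
    )


def _downscale_mask(raster: np.ndarray) -> np.ndarray:
    # any-foreground pooling keeps 1-px-thin features alive
    return block_reduce(raster, (2, 2), np.max).astype(bool)


def _downscale_image(image: np.ndarray) -> np.ndarray:
    return block_reduce(image.astype(np.float64), (2, 2), np.mean).astype(image.dtype)


def mosaic_augment(
    samples: Sequence[Tuple[np.ndarray, Sequence[InstanceMask]]],
    seed: int = 0,
) -> Tuple[np.ndarray, List[InstanceMask]]:
    """Compose four samples into the quadrants of one image.

    Each input is downscaled by 2 (area pooling for intensities,
    any-foreground pooling for masks) and placed into a seeded-random
    quadrant of an output frame of the original size; annotations are
    scaled and offset accordingly, so the output carries the union of all
    four annotation sets.
    """
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly four samples")
    size = samples[0][0].shape[0]
    for img, _ in samples:
        if img.shape != (size, size):
            raise ValueError("mosaic samples must be same-sized squares")
    if size % 2 != 0:
        raise ValueError("mosaic needs an even frame size")
    half = size // 2
    rng = np.random.default_rng(seed)
    order = rng.permutation(4)
    offsets = [(0, 0), (0, half), (half, 0), (half, half)]  # (row, col)
    out_img = np.zeros((size, size), dtype=samples[0][0].dtype)
    out_masks: List[InstanceMask] = []
    for quadrant, sample_idx in enumerate(order):
        img, masks = samples[sample_idx]
        r0, c0 = offsets[quadrant]
        out_img[r0 : r0 + half, c0 : c0 + half] = _downscale_image(img)
        for m in masks:
            small = _downscale_mask(m.raster)
            placed = np.zeros((size, size), dtype=bool)
            placed[r0 : r0 + half, c0 : c0 + half] = small
            out_masks.append(InstanceMask(placed, m.label, m.score))
    return out_img, out_masks


def mosaic_box(box: BoundingBox, quadrant: int, size: int) -> BoundingBox:
    """Direct box transform for quadrant placement (oracle for tests)."""
    half = size // 2
    offsets = [(0, 0), (0, half), (half, 0), (half, half)]
    r0, c0 = offsets[quadrant]
    small = downscale_box(box)
    return BoundingBox(
        small.x_min + c0, small.y_min + r0, small.x_max + c0, small.y_max + r0
    )


# ---------------------------------------------------------------------------
# Weak annotations from masks
# ---------------------------------------------------------------------------

def masks_to_detector_annotations(
    masks: Sequence[InstanceMask],
) -> List[Dict]:
    """One circumscribing box + label per mask — the weak-annotation step
    that lets a detector train without pixel-wise labels."""
    records = []
    for m in masks:
        box = bbox_from_mask(m)  # raises on empty masks
        records.append({"label": m.label, "box": box})
    return records


def expand_training_set(
    samples: Sequence[Tuple[np.ndarray, Sequence[InstanceMask]]],
    config: AugmentationConfig,
) -> List[Tuple[np.ndarray, List[InstanceMask]]]:
    """Originals + rotations (+ mosaics), optionally subsampled to
    ``target_total`` with a seeded choice.

    Emitting all three rotation directions per image is a deterministic
    superset of random direction choice; ``target_total`` supports
    reproducing a fixed augmented-set size when a subsample is wanted.
    """
    pool: List[Tuple[np.ndarray, List[InstanceMask]]] = [
        (img, list(masks)) for img, masks in samples
    ]
    for img, masks in samples:
        for _, rimg, rmasks in rotate_augment(img, masks):
            if any(m.is_empty for m in rmasks):
                continue
            pool.append((rimg, rmasks))
    if config.mosaic and len(samples) >= 4:
        rng = np.random.default_rng(config.seed)
        n_mosaics = max(1, len(samples) // 4)
        for k in range(n_mosaics):
            idx = rng.choice(len(samples), size=4, replace=False)
            pool.append(
                mosaic_augment(
                    [samples[i] for i in idx], seed=int(rng.integers(2**31))
                )
            )
    if config.target_total is not None and config.target_total < len(pool):
        rng = np.random.default_rng(config.seed + 1)
        originals = len(samples)
        extra = rng.choice(
            np.arange(originals, len(pool)),
            size=config.target_total - originals,
            replace=False,
        )
        keep = list(range(originals)) + sorted(int(i) for i in extra)
        pool = [pool[i] for i in keep]
    return pool
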