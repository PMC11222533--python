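"""Seeded synthetic basement-membrane-style scenes with ground truth.

The generator emulates the phenomena that motivate enhanced prompting in
myocardial cross-sections: large non-convex cardiomyocyte (CM) profiles
tessellating the frame, outlined by bright membrane ridges over dark
interiors, with small capillary (CAP) rings wedged at CM junctions. In
such scenes CM bounding boxes overlap each other and CAP boxes are
frequently enclosed by CM boxes, so box prompts alone are ambiguous.

Construction, fully determined by (spec, seed):

1. CM seeds on a jittered grid; the frame is partitioned by nearest-seed
   assignment under a per-seed smooth noise field added to the distance
   transform — ``shape_irregularity`` scales the noise amplitude, turning
   convex Voronoi cells into lobed non-convex profiles.
2. Each CM ground-truth mask is its region eroded by the membrane
   thickness, so adjacent interiors are separated by a ridge band.
3. Capillaries are stamped at boundary/junction points of the
   tessellation: a dark lumen disk (the CAP ground truth) inside a bright
   ring, carved out of the host CM masks so all ground-truth masks are
   pairwise disjoint.
4. Rendering: dark interiors, bright ridges everywhere outside interiors,
   mild blur, optional additive Gaussian noise (16-bit counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .geometry import (
    BoundingBox,
    ClassLabel,
    ImageMeta,
    InstanceMask,
    bbox_from_mask,
    box_contains_box,
    box_iou,
)

INTERIOR_LEVEL = 6000  # 16-bit counts of dark object interiors
RIDGE_LEVEL = 45000  # 16-bit counts of bright membrane ridges
BLUR_SIGMA_PX = 0.6


@dataclass(frozen=True)
class SceneSpec:
    n_cm: int = 6
    caps_per_cm: float = 2.0
    shape_irregularity: float = 0.6
    membrane_thickness_px: int = 3
    noise_sd: float = 1500.0  # additive Gaussian noise, 16-bit counts
    meta: ImageMeta = field(default_factory=ImageMeta)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cm < 1:
            raise ValueError("need at least one CM profile")
        if not (0.0 <= self.shape_irregularity <= 1.0):
            raise ValueError("shape_irregularity must lie in [0, 1]")
        if self.membrane_thickness_px < 1:
            raise ValueError("membrane thickness must be >= 1 px")
        if self.caps_per_cm < 0 or self.noise_sd < 0:
            raise ValueError("caps_per_cm and noise_sd must be >= 0")


def default_scene_spec(seed: int = 0, size: int = 512) -> SceneSpec:
    """The dense-packing study condition (lobed profiles, noisy render)."""
    return SceneSpec(seed=seed, meta=_meta_for(size))


def easy_scene_spec(seed: int = 0, size: int = 256) -> SceneSpec:
    """Low-irregularity, noise-free preset used for closed-loop checks."""
    return SceneSpec(
        n_cm=6,
        caps_per_cm=2.0,
        shape_irregularity=0.2,
        noise_sd=0.0,
        seed=seed,
        meta=_meta_for(size),
    )


def _meta_for(size: int) -> ImageMeta:
    # keep the acquisition pixel pitch (42.5 um over 512 px) at any size
    fov = 42.5 * size / 512.0
    return ImageMeta(width_px=size, height_px=size, fov_um=(fov, fov))


def _cm_seed_points(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.meta.shape
    cols = int(np.ceil(np.sqrt(spec.n_cm * w / h)))
    rows = int(np.ceil(spec.n_cm / cols))
    if rows * cols < spec.n_cm:
        cols += 1
    cell_w, cell_h = w / cols, h / rows
    if min(cell_w, cell_h) < 6 * spec.membrane_thickness_px:
        raise ValueError("infeasible spec: too many CM profiles for the frame")
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    chosen = rng.permutation(len(cells))[: spec.n_cm]
    pts = []
    for k in chosen:
        r, c = cells[k]
        x = (c + 0.5) * cell_w + rng.uniform(-0.25, 0.25) * cell_w
        y = (r + 0.5) * cell_h + rng.uniform(-0.25, 0.25) * cell_h
        pts.append((x, y))
    return np.asarray(pts)


def _tessellate(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-pixel CM region labels in 0..n_cm-1."""
    h, w = spec.meta.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    seeds = _cm_seed_points(spec, rng)
    cell = np.sqrt(h * w / spec.n_cm)
    amp = spec.shape_irregularity * 0.35 * cell
    sigma = max(cell / 5.0, 4.0)
    cost = np.empty((spec.n_cm, h, w), dtype=np.float32)
    for i, (sx, sy) in enumerate(seeds):
        dist = np.hypot(xx - sx, yy - sy)
        noise = gaussian_filter(
            rng.standard_normal((h, w)).astype(np.float32), sigma
        )
        noise /= max(noise.std(), 1e-9)
        cost[i] = dist + amp * noise
    return np.argmin(cost, axis=0)


def _junction_candidates(labels: np.ndarray, margin: int) -> np.ndarray:
    """Boundary points of the tessellation, junctions (>=3 regions) first."""
    h, w = labels.shape
    a = labels[:-1, :-1]
    b = labels[:-1, 1:]
    c = labels[1:, :-1]
    d = labels[1:, 1:]
    stacked = np.stack([a, b, c, d])
    n_distinct = (
        1
        + (b != a).astype(np.int8)
        + ((c != a) & (c != b)).astype(np.int8)
        + ((d != a) & (d != b) & (d != c)).astype(np.int8)
    )
    del stacked
    inside = np.zeros_like(n_distinct, dtype=bool)
    inside[margin : h - margin, margin : w - margin] = True
    junctions = np.argwhere((n_distinct >= 3) & inside)
    edges = np.argwhere((n_distinct == 2) & inside)
    return junctions, edges


def _place_capillaries(
    spec: SceneSpec,
    labels: np.ndarray,
    rng: np.random.Generator,
) -> List[Tuple[int, int, int]]:
    """Choose (row, col, lumen_radius) for each capillary, well separated."""
    n_cap = int(round(spec.caps_per_cm * spec.n_cm))
    if n_cap == 0:
        return []
    size = spec.meta.width_px
    r_lo = max(3, int(round(5 * size / 512.0)))
    r_hi = max(r_lo + 1, int(round(9 * size / 512.0)))
    margin = r_hi + spec.membrane_thickness_px + 3
    junctions, edges = _junction_candidates(labels, margin)
    candidates = np.concatenate(
        [
            junctions[rng.permutation(len(junctions))],
            edges[rng.permutation(len(edges))],
        ]
    ) if len(junctions) or len(edges) else np.empty((0, 2), dtype=int)
    min_sep = 2 * (r_hi + spec.membrane_thickness_px) + 2
    placed: List[Tuple[int, int, int]] = []
    for rr, cc in candidates:
        if len(placed) >= n_cap:
            break
        if all((rr - pr) ** 2 + (cc - pc) ** 2 >= min_sep**2 for pr, pc, _ in placed):
            placed.append((int(rr), int(cc), int(rng.integers(r_lo, r_hi + 1))))
    if len(placed) < n_cap:
        raise ValueError(
            f"infeasible spec: placed only {len(placed)} of {n_cap} capillaries"
        )
    return placed


def generate_scene(spec: SceneSpec) -> Tuple[np.ndarray, List[InstanceMask]]:
    """Render one scene; returns (16-bit image, ground-truth masks).

    Masks are pairwise disjoint, each non-empty, CM instances first then
    CAP instances. Identical (spec, seed) inputs reproduce identical
    outputs bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.meta.shape
    labels = _tessellate(spec, rng)
    selem = np.ones(
        (2 * spec.membrane_thickness_px // 2 + 1,) * 2, dtype=bool
    )
    half = max(spec.membrane_thickness_px // 2, 1)
    selem = np.ones((2 * half + 1, 2 * half + 1), dtype=bool)
    cm_rasters = []
    for i in range(spec.n_cm):
        interior = binary_erosion(labels == i, structure=selem)
        if not interior.any():
            raise ValueError("infeasible spec: a CM profile vanished under erosion")
        cm_rasters.append(interior)

    caps = _place_capillaries(spec, labels, rng)
    yy, xx = np.mgrid[0:h, 0:w]
    cap_rasters = []
    for rr, cc, radius in caps:
        d2 = (yy - rr) ** 2 + (xx - cc) ** 2
        lumen = d2 <= radius**2
        footprint = d2 <= (radius + spec.membrane_thickness_px) ** 2
        for i in range(len(cm_rasters)):
            cm_rasters[i] = cm_rasters[i] & ~footprint
        cap_rasters.append(lumen)
    for i, raster in enumerate(cm_rasters):
        if not raster.any():
            raise ValueError("infeasible spec: a CM profile vanished under carving")

    interiors = np.zeros((h, w), dtype=bool)
    for raster in cm_rasters + cap_rasters:
        interiors |= raster
    img = np.where(interiors, float(INTERIOR_LEVEL), float(RIDGE_LEVEL))
    img = gaussian_filter(img, BLUR_SIGMA_PX)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    image = np.clip(img, 0, 65535).astype(np.uint16)

    masks = [InstanceMask(r, ClassLabel.CM) for r in cm_rasters] + [
        InstanceMask(r, ClassLabel.CAP) for r in cap_rasters
    ]
    return image, masks


def scene_statistics(masks: Sequence[InstanceMask]) -> Dict[str, float]:
    """Dense-packing statistics of one annotation set.

    Reports the per-label counts, the fraction of CAP boxes fully enclosed
    by at least one CM box, and the fraction of CM box pairs that overlap
    — the quantities that make fine (point) constraints necessary.
    """
    cm_boxes = [bbox_from_mask(m) for m in masks if m.label == ClassLabel.CM]
    cap_boxes = [bbox_from_mask(m) for m in masks if m.label == ClassLabel.CAP]
    n_pairs = len(cm_boxes) * (len(cm_boxes) - 1) // 2
    n_overlap = sum(
        1
        for i in range(len(cm_boxes))
        for j in range(i + 1, len(cm_boxes))
        if box_iou(cm_boxes[i], cm_boxes[j]) > 0
    )
    n_enclosed = sum(
        1
        for cap in cap_boxes
        if any(box_contains_box(cm, cap) for cm in cm_boxes)
    )
    return {
        "n_cm": len(cm_boxes),
        "n_cap": len(cap_boxes),
        "cap_enclosed_fraction": (n_enclosed / len(cap_boxes)) if cap_boxes else 0.0,
        "cm_box_overlap_rate": (n_overlap / n_pairs) if n_pairs else 0.0,
    }
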