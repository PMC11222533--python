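"""Capillarization-related measurements from labelled instance masks.

Seven quantities per image: the counts and total areas of cardiomyocytes
(CM) and capillaries (CAP), and three densities —

* CDFA: capillary density per FOV area   = n_cap / FOV area      (um^-2)
* CDCA: capillary density per CM area    = n_cap / total CM area (um^-2)
* CCR : capillary-to-cardiomyocyte ratio = n_cap / n_cm

CDCA and CCR are undefined when their denominators vanish; undefined
values are carried as explicit None markers, never silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from .evaluation import relative_error
from .geometry import ClassLabel, ImageMeta, InstanceMask, mask_area_um2

MEASUREMENT_NAMES = (
    "n_cm",
    "n_cap",
    "area_cm_um2",
    "area_cap_um2",
    "cdfa_per_um2",
    "cdca_per_um2",
    "ccr",
)


@dataclass
class CapillarizationReport:
    n_cm: int
    n_cap: int
    area_cm_um2: float
    area_cap_um2: float
    cdfa_per_um2: float
    cdca_per_um2: Optional[float]  # None when total CM area is 0
    ccr: Optional[float]  # None when n_cm is 0
    fov_area_um2: float
    area_mode: str = "per_mask"

    def as_dict(self) -> Dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in MEASUREMENT_NAMES}


def assess(
    masks: Sequence[InstanceMask],
    meta: ImageMeta,
    area_mode: str = "per_mask",
) -> CapillarizationReport:
    """Derive the seven measurements from one image's instance masks.

    ``area_mode='per_mask'`` sums each mask's area independently (the
    default: each instance is measured on its own, so overlapping
    predictions each count); ``'union'`` measures the union footprint per
    label instead.
    """
    if area_mode not in ("per_mask", "union"):
        raise ValueError(f"unknown area_mode {area_mode!r}")
    for m in masks:
        if m.raster.shape != meta.shape:
            raise ValueError("mask dimensions do not match image meta")
    cm = [m for m in masks if m.label == ClassLabel.CM]
    cap = [m for m in masks if m.label == ClassLabel.CAP]
    if area_mode == "per_mask":
        area_cm = sum(mask_area_um2(m, meta) for m in cm)
        area_cap = sum(mask_area_um2(m, meta) for m in cap)
    else:
        area_cm = _union_area(cm, meta)
        area_cap = _union_area(cap, meta)
    n_cm, n_cap = len(cm), len(cap)
    return CapillarizationReport(
        n_cm=n_cm,
        n_cap=n_cap,
        area_cm_um2=float(area_cm),
        area_cap_um2=float(area_cap),
        cdfa_per_um2=n_cap / meta.fov_area_um2,
        cdca_per_um2=(n_cap / area_cm) if area_cm > 0 else None,
        ccr=(n_cap / n_cm) if n_cm > 0 else None,
        fov_area_um2=meta.fov_area_um2,
        area_mode=area_mode,
    )


def _union_area(masks: Sequence[InstanceMask], meta: ImageMeta) -> float:
    if not masks:
        return 0.0
    union = np.zeros(meta.shape, dtype=bool)
    for m in masks:
        union |= m.raster
    return float(union.sum()) * meta.pixel_area_um2


def report_errors(
    predicted: CapillarizationReport, truth: CapillarizationReport
) -> Dict[str, Optional[float]]:
    """Per-measurement relative errors delta = |pred - truth| / truth.

    A measurement is skipped (None) when the truth value is zero or when
    either side is undefined; skipped entries are flagged, not dropped.
    """
    if predicted.fov_area_um2 != truth.fov_area_um2:
        raise ValueError("reports come from different image geometries")
    errors: Dict[str, Optional[float]] = {}
    for name in MEASUREMENT_NAMES:
        p = getattr(predicted, name)
        t = getattr(truth, name)
        if p is None or t is None or t == 0:
            errors[name] = None
        else:
            errors[name] = relative_error(float(p), float(t))
    return errors
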