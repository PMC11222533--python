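"""Object-detector contract with a ground-truth-backed oracle adapter.

A production detector would be a trained YOLOv8-family model; here the
detector is an adapter slot behind a registry, because the method's
substance is prompt engineering and measurement, not the detector. The
built-in ``oracle`` adapter derives detections from ground-truth masks
(optionally jittered) so the whole pipeline runs and is testable without
any trained weights or GPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import (
    BoundingBox,
    ClassLabel,
    EmptyMaskError,
    InstanceMask,
    bbox_from_mask,
)


@dataclass(frozen=True)
class Detection:
    box: BoundingBox
    label: ClassLabel
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence out of range: {self.confidence}")


DetectionSet = List[Detection]


@dataclass
class DetectorConfig:
    """Inference-time settings for a detector adapter."""

    adapter_name: str = "oracle"
    confidence_threshold: float = 0.0
    max_detections: int = 300
    # adapter-specific options, e.g. {"jitter_px": 2.0, "seed": 7,
    # "annotations": [...]} for the oracle adapter
    options: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.max_detections <= 0:
            raise ValueError("max_detections must be positive")


AdapterFn = Callable[[np.ndarray, DetectorConfig], DetectionSet]

_ADAPTERS: Dict[str, AdapterFn] = {}


def register_adapter(name: str, fn: AdapterFn) -> None:
    _ADAPTERS[name] = fn


def available_adapters() -> List[str]:
    return sorted(_ADAPTERS)


def sort_detections(detections: Sequence[Detection]) -> DetectionSet:
    """Stable ordering: confidence descending, then x_min, then y_min."""
    return sorted(
        detections, key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min)
    )


def detect(image: np.ndarray, config: DetectorConfig) -> DetectionSet:
    """Run the configured adapter and normalize its output.

    Output detections are confidence-filtered, sorted by descending
    confidence (ties broken by box position), truncated to
    ``max_detections``, and clipped to the image bounds.
    """
    if config.adapter_name not in _ADAPTERS:
        raise KeyError(
            f"unknown detector adapter {config.adapter_name!r}; "
            f"registered: {available_adapters()}"
        )
    raw = _ADAPTERS[config.adapter_name](image, config)
    kept = [d for d in raw if d.confidence >= config.confidence_threshold]
    kept = sort_detections(kept)[: config.max_detections]
    h, w = image.shape[:2]
    return [_clip_detection(d, w, h) for d in kept]


def _clip_detection(d: Detection, width: int, height: int) -> Detection:
    box = clip_box(d.box, width, height)
    return Detection(box=box, label=d.label, confidence=d.confidence)


def clip_box(box: BoundingBox, width: int, height: int) -> BoundingBox:
    """Clip to image bounds, preserving a minimal 1-px extent."""
    x_min = min(max(box.x_min, 0.0), width - 1.0)
    y_min = min(max(box.y_min, 0.0), height - 1.0)
    x_max = max(min(box.x_max, float(width)), x_min + 1.0)
    y_max = max(min(box.y_max, float(height)), y_min + 1.0)
    return BoundingBox(x_min, y_min, x_max, y_max)


def oracle_detector(
    annotations: Sequence[InstanceMask],
    jitter_px: float = 0.0,
    seed: Optional[int] = None,
    image_shape: Optional[Tuple[int, int]] = None,
) -> DetectionSet:
    """Derive detections from ground-truth masks.

    Each mask contributes one detection: its circumscribing box, its label,
    confidence 1.0. ``jitter_px`` perturbs every box edge independently by
    a uniform offset in [-j, +j] pixels (seeded), emulating an imperfect
    detector while keeping the closed loop free of any trained model.
    """
    rng = np.random.default_rng(seed)
    detections: DetectionSet = []
    for mask in annotations:
        if mask.is_empty:
            raise EmptyMaskError("oracle detector requires non-empty masks")
        box = bbox_from_mask(mask)
        if jitter_px > 0:
            dx0, dy0, dx1, dy1 = rng.uniform(-jitter_px, jitter_px, size=4)
            box = BoundingBox(
                box.x_min + dx0,
                box.y_min + dy0,
                max(box.x_max + dx1, box.x_min + dx0 + 1.0),
                max(box.y_max + dy1, box.y_min + dy0 + 1.0),
            )
        if image_shape is not None:
            h, w = image_shape
            box = clip_box(box, w, h)
        detections.append(Detection(box=box, label=mask.label, confidence=1.0))
    return sort_detections(detections)


def _oracle_adapter(image: np.ndarray, config: DetectorConfig) -> DetectionSet:
    annotations = config.options.get("annotations")
    if annotations is None:
        return []
    return oracle_detector(
        annotations,
        jitter_px=float(config.options.get("jitter_px", 0.0)),
        seed=config.options.get("seed"),
        image_shape=image.shape[:2],
    )


register_adapter("oracle", _oracle_adapter)


def _yolo_adapter(image: np.ndarray, config: DetectorConfig) -> DetectionSet:
    """Optional slot for a trained YOLO-family detector (requires
    ultralytics and a weights file; never exercised by the test suite)."""
    try:
        from ultralytics import YOLO  # type: ignore
    except ImportError as exc:  # pragma: no cover
        raise RuntimeError(
            "the 'yolo' adapter requires the optional ultralytics package "
            "and a trained weights file ('weights' option)"
        ) from exc
    weights = config.options.get("weights")  # pragma: no cover
    if not weights:  # pragma: no cover
        raise RuntimeError("the 'yolo' adapter needs a 'weights' option")
    model = YOLO(weights)  # pragma: no cover
    result = model.predict(image, verbose=False)[0]  # pragma: no cover
    detections = []  # pragma: no cover
    for xyxy, conf, cls in zip(  # pragma: no cover
        result.boxes.xyxy.tolist(),
        result.boxes.conf.tolist(),
        result.boxes.cls.tolist(),
    ):
        label = ClassLabel.CM if int(cls) == 0 else ClassLabel.CAP
        detections.append(
            Detection(BoundingBox(*xyxy), label, float(conf))
        )
    return detections  # pragma: no cover


register_adapter("yolo", _yolo_adapter)
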