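"""End-to-end orchestration: detect -> prompt -> segment -> measure.

The flow mirrors the two-block architecture: the prompt-learning block
(detector + prompt generator, which also carries the class labels) and the
promptable segmentation block, followed by capillarization measurement and
evaluation. Class labels are assigned only by the detector; masks inherit
them through their prompts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import capillarization as cap
from .detection import Detection, DetectorConfig, detect
from .evaluation import (
    PRESETS,
    EvalReport,
    aggregate_runs,
    evaluate_dataset,
)
from .geometry import ClassLabel, ImageMeta, InstanceMask
from .prompts import PromptSet, generate_prompts
from .segmentation import SegmentationResult, segment_with_prompts

logger = logging.getLogger("capquant")

EXIT_OK = 0
EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_STAGE_FAILURE = 4


class StageError(RuntimeError):
    """Failure in a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    backend: str = "reference"
    meta: ImageMeta = field(default_factory=ImageMeta)
    strict_coco: bool = False
    area_mode: str = "per_mask"
    seed: int = 0
    n_runs: int = 5
    log_level: str = "INFO"

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["meta"] = {
            "width_px": self.meta.width_px,
            "height_px": self.meta.height_px,
            "fov_um": list(self.meta.fov_um),
            "bit_depth": self.meta.bit_depth,
        }
        return d

    @staticmethod
    def from_dict(d: Dict) -> "PipelineConfig":
        d = dict(d)
        if "meta" in d:
            m = dict(d["meta"])
            m["fov_um"] = tuple(m.get("fov_um", (42.5, 42.5)))
            d["meta"] = ImageMeta(**m)
        if "detector" in d and isinstance(d["detector"], dict):
            d["detector"] = DetectorConfig(**d["detector"])
        return PipelineConfig(**d)


def predict(
    image: np.ndarray,
    config: PipelineConfig,
    annotations: Optional[Sequence[InstanceMask]] = None,
) -> Tuple[List[Detection], List[PromptSet], SegmentationResult]:
    """Run detection, prompt generation and prompted segmentation.

    ``annotations`` feed the oracle detector adapter; a trained adapter
    ignores them. Predicted masks carry the confidence of their source
    detection.
    """
    det_config = config.detector
    if annotations is not None:
        det_config = dataclasses.replace(
            det_config,
            options={**det_config.options, "annotations": list(annotations)},
        )
    try:
        detections = detect(image, det_config)
    except Exception as exc:
        raise StageError("detect", exc) from exc
    try:
        prompts = generate_prompts(detections)
    except Exception as exc:
        raise StageError("generate_prompts", exc) from exc
    try:
        result = segment_with_prompts(image, prompts, backend=config.backend)
    except Exception as exc:
        raise StageError("segment", exc) from exc
    for mask, prompt in zip(result.instances, prompts):
        mask.score = detections[prompt.source_index].confidence
        assert mask.label == detections[prompt.source_index].label
    logger.info(
        "predict: %d detections, %d prompt points, %d failed predictions",
        len(detections),
        sum(len(p.points) for p in prompts),
        result.n_failed,
    )
    return detections, prompts, result


def assess_image(
    image: np.ndarray,
    config: PipelineConfig,
    annotations: Optional[Sequence[InstanceMask]] = None,
) -> cap.CapillarizationReport:
    """Predict instances, then derive capillarization measurements from
    the non-failed predicted masks."""
    _, _, result = predict(image, config, annotations)
    report = cap.assess(
        result.valid_instances(), config.meta, area_mode=config.area_mode
    )
    if report.ccr is None or report.cdca_per_um2 is None:
        logger.warning("assess: CDCA/CCR undefined (no CM mass predicted)")
    return report


@dataclass
class BenchmarkReport:
    """Per-run metric and error tables plus mean +- SD aggregation."""

    per_run_metrics: List[Dict[str, Dict[str, float]]]
    per_run_errors: List[Dict[str, Optional[float]]]
    metric_summary: Dict[str, Dict[str, Tuple[float, float]]]
    error_summary: Dict[str, Tuple[float, float]]
    eval_reports: List[EvalReport]


def run_benchmark(
    dataset: Sequence[Tuple[np.ndarray, Sequence[InstanceMask]]],
    config: PipelineConfig,
    n_runs: Optional[int] = None,
) -> BenchmarkReport:
    """Repeat predict+evaluate over n_runs seeded runs and aggregate.

    Each run re-seeds the stochastic stages (e.g. oracle box jitter) from
    ``config.seed + run``; per-run mAP/mAR/F1 for every threshold setting
    and per-run mean relative errors of the seven capillarization
    measurements are collected and reported as mean +- sample SD.
    """
    if not dataset:
        raise ValueError("benchmark needs a dataset with ground truth")
    n_runs = n_runs if n_runs is not None else config.n_runs
    per_run_metrics = []
    per_run_errors = []
    eval_reports = []
    for run in range(n_runs):
        run_config = dataclasses.replace(
            config,
            detector=dataclasses.replace(
                config.detector,
                options={**config.detector.options, "seed": config.seed + run},
            ),
        )
        pairs = []
        deltas: Dict[str, List[float]] = {
            name: [] for name in cap.MEASUREMENT_NAMES
        }
        for image, gts in dataset:
            _, _, result = predict(image, run_config, annotations=gts)
            preds = result.instances
            pairs.append((preds, list(gts)))
            pred_report = cap.assess(
                result.valid_instances(), config.meta, config.area_mode
            )
            gt_report = cap.assess(list(gts), config.meta, config.area_mode)
            for name, delta in cap.report_errors(pred_report, gt_report).items():
                if delta is not None:
                    deltas[name].append(delta)
        report = evaluate_dataset(pairs, PRESETS, strict_coco=config.strict_coco)
        eval_reports.append(report)
        per_run_metrics.append(report.summary())
        per_run_errors.append(
            {
                name: (float(np.mean(v)) if v else None)
                for name, v in deltas.items()
            }
        )
    metric_summary: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for setting in PRESETS:
        metric_summary[setting] = {}
        for metric in ("mAP", "mAR", "F1"):
            values = [m[setting][metric] for m in per_run_metrics]
            metric_summary[setting][metric] = (
                aggregate_runs(values) if len(values) >= 2 else (values[0], 0.0)
            )
    error_summary: Dict[str, Tuple[float, float]] = {}
    for name in cap.MEASUREMENT_NAMES:
        values = [e[name] for e in per_run_errors if e[name] is not None]
        if len(values) >= 2:
            error_summary[name] = aggregate_runs(values)
        elif values:
            error_summary[name] = (values[0], 0.0)
    return BenchmarkReport(
        per_run_metrics=per_run_metrics,
        per_run_errors=per_run_errors,
        metric_summary=metric_summary,
        error_summary=error_summary,
        eval_reports=eval_reports,
    )
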