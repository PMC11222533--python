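"""Instance-segmentation evaluation and run aggregation.

Outcome classification follows the four-way rule used for this workflow,
applied to a matched prediction/ground-truth pair at IoU threshold phi:

* labels identical,  IoU >= phi  ->  TP
* labels identical,  IoU <  phi  ->  FP
* labels different,  IoU >= phi  ->  TN
* labels different,  IoU <  phi  ->  FN

Note this departs from strict COCO convention (where a label mismatch is
simply a failed match); it is implemented verbatim, with a strict-COCO
mode available behind a flag for comparability (default off).

Matching is one-to-one and greedy by descending IoU, computed
label-agnostically; unmatched predictions are FP and unmatched ground
truths FN. Precision and recall use TP/FP/FN only; TN is tallied and
reported. mAP/mAR average over the two labels (and over the ten
thresholds in the [0.5:0.95] sweep); F1 is the harmonic mean of mAP and
mAR. Average precision integrates a score-ranked precision-recall curve
(COCO 101-point) when confidence scores exist, otherwise the operating
point's set-level precision is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .geometry import ClassLabel, InstanceMask, mask_iou

SINGLE_50 = (0.5,)
SINGLE_75 = (0.75,)
SWEEP_50_95 = tuple(round(0.5 + 0.05 * k, 2) for k in range(10))

PRESETS: Dict[str, Tuple[float, ...]] = {
    "iou_0.50": SINGLE_50,
    "iou_0.75": SINGLE_75,
    "iou_0.50:0.95": SWEEP_50_95,
}


@dataclass(frozen=True)
class EvalConfig:
    thresholds: Tuple[float, ...] = SINGLE_50
    strict_coco: bool = False

    def __post_init__(self) -> None:
        if not all(0.0 < t <= 1.0 for t in self.thresholds):
            raise ValueError("IoU thresholds must lie in (0, 1]")


@dataclass
class OutcomeCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def classify_outcome(m_p: InstanceMask, m_gt: InstanceMask, phi: float) -> str:
    """Classify one prediction/ground-truth pair under the four-way rule."""
    iou = mask_iou(m_p, m_gt)
    same_label = m_p.label == m_gt.label
    if same_label:
        return "TP" if iou >= phi else "FP"
    return "TN" if iou >= phi else "FN"


def greedy_match(
    preds: Sequence[InstanceMask],
    gts: Sequence[InstanceMask],
    same_label_only: bool = False,
) -> List[Tuple[int, int, float]]:
    """One-to-one greedy assignment by descending IoU.

    Returns (pred_index, gt_index, iou) triples for pairs with IoU > 0.
    Ties broken deterministically by (pred index, gt index).
    """
    pairs = []
    for pi, p in enumerate(preds):
        if p.is_empty:
            continue
        for gi, g in enumerate(gts):
            if same_label_only and p.label != g.label:
                continue
            iou = mask_iou(p, g)
            if iou > 0:
                pairs.append((iou, pi, gi))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_p: set = set()
    used_g: set = set()
    matches = []
    for iou, pi, gi in pairs:
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        matches.append((pi, gi, iou))
    return matches


@dataclass
class ImageEval:
    """Matching result for one image, reusable across thresholds."""

    matches: List[Tuple[int, int, float]]
    pred_labels: List[ClassLabel]
    gt_labels: List[ClassLabel]
    pred_scores: List[Optional[float]]
    same_label: List[bool]
    n_dropped_empty: int


def match_predictions(
    preds: Sequence[InstanceMask],
    gts: Sequence[InstanceMask],
    strict_coco: bool = False,
) -> ImageEval:
    """Match one image's predictions to its ground truths.

    Empty (failed) predictions are dropped before matching; their ground
    truths consequently surface as FN.
    """
    matches = greedy_match(preds, gts, same_label_only=strict_coco)
    return ImageEval(
        matches=matches,
        pred_labels=[p.label for p in preds],
        gt_labels=[g.label for g in gts],
        pred_scores=[p.score for p in preds],
        same_label=[
            preds[pi].label == gts[gi].label for pi, gi, _ in matches
        ],
        n_dropped_empty=sum(1 for p in preds if p.is_empty),
    )


def outcome_counts(
    ev: ImageEval, phi: float, label: Optional[ClassLabel] = None
) -> OutcomeCounts:
    """Tally the four-way outcomes of one image at one threshold.

    TP/FP attach to the prediction's label, FN to the ground truth's; TN
    (label mismatch at high IoU) is tallied under the prediction's label.
    """
    counts = OutcomeCounts()
    matched_p = {pi for pi, _, _ in ev.matches}
    matched_g = {gi for _, gi, _ in ev.matches}
    for (pi, gi, iou), same in zip(ev.matches, ev.same_label):
        if same:
            if iou >= phi:
                if label is None or ev.pred_labels[pi] == label:
                    counts.tp += 1
            else:
                if label is None or ev.pred_labels[pi] == label:
                    counts.fp += 1
        else:
            if iou >= phi:
                if label is None or ev.pred_labels[pi] == label:
                    counts.tn += 1
            else:
                if label is None or ev.gt_labels[gi] == label:
                    counts.fn += 1
    for pi, plabel in enumerate(ev.pred_labels):
        if pi not in matched_p and (label is None or plabel == label):
            counts.fp += 1
    for gi, glabel in enumerate(ev.gt_labels):
        if gi not in matched_g and (label is None or glabel == label):
            counts.fn += 1
    return counts


def _precision_recall(c: OutcomeCounts) -> Tuple[float, float]:
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return precision, recall


def _average_precision_ranked(
    tp_flags: Sequence[bool], scores: Sequence[float], n_gt: int
) -> float:
    """COCO 101-point interpolated AP from score-ranked predictions."""
    if n_gt == 0 or len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-np.asarray(scores, dtype=float), kind="stable")
    flags = np.asarray(tp_flags, dtype=bool)[order]
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    # precision envelope (monotone non-increasing from the right)
    for i in range(precision.size - 1, 0, -1):
        precision[i - 1] = max(precision[i - 1], precision[i])
    levels = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, levels, side="left")
    interp = np.where(idx < recall.size, precision[np.minimum(idx, recall.size - 1)], 0.0)
    return float(interp.mean())


@dataclass
class SettingMetrics:
    mAP: float
    mAR: float
    f1: float
    per_label: Dict[str, Dict[str, float]]
    counts: Dict[str, Dict[float, OutcomeCounts]]
    ap_mode: str  # "score_ranked" or "set_level"


@dataclass
class EvalReport:
    settings: Dict[str, SettingMetrics]
    n_images: int
    n_dropped_empty: int

    def summary(self) -> Dict[str, Dict[str, float]]:
        return {
            name: {"mAP": m.mAP, "mAR": m.mAR, "F1": m.f1}
            for name, m in self.settings.items()
        }


def _harmonic(p: float, r: float) -> float:
    return 2 * p * r / (p + r) if (p + r) > 0 else 0.0


def compute_metrics(
    image_evals: Sequence[ImageEval],
    config: EvalConfig = EvalConfig(),
    setting_name: str = "iou_0.50",
) -> SettingMetrics:
    """Aggregate per-image matchings into mAP/mAR/F1 for one setting."""
    if not image_evals or all(not ev.gt_labels for ev in image_evals):
        raise ValueError("no ground truth to evaluate against")
    labels = [ClassLabel.CM, ClassLabel.CAP]
    have_scores = all(
        s is not None for ev in image_evals for s in ev.pred_scores
    )
    ap_per_label_phi: Dict[str, Dict[float, float]] = {l.value: {} for l in labels}
    recall_per_label_phi: Dict[str, Dict[float, float]] = {l.value: {} for l in labels}
    counts_out: Dict[str, Dict[float, OutcomeCounts]] = {l.value: {} for l in labels}
    for label in labels:
        n_gt = sum(
            1 for ev in image_evals for g in ev.gt_labels if g == label
        )
        for phi in config.thresholds:
            total = OutcomeCounts()
            tp_flags: List[bool] = []
            scores: List[float] = []
            for ev in image_evals:
                total = total + outcome_counts(ev, phi, label)
                if have_scores:
                    matched_tp = {
                        pi
                        for (pi, gi, iou), same in zip(ev.matches, ev.same_label)
                        if same and iou >= phi
                    }
                    for pi, plabel in enumerate(ev.pred_labels):
                        if plabel == label:
                            tp_flags.append(pi in matched_tp)
                            scores.append(float(ev.pred_scores[pi]))
            precision, recall = _precision_recall(total)
            if have_scores:
                ap = _average_precision_ranked(tp_flags, scores, n_gt)
            else:
                ap = precision
            ap_per_label_phi[label.value][phi] = ap
            recall_per_label_phi[label.value][phi] = recall
            counts_out[label.value][phi] = total
    label_ap = {
        l: float(np.mean(list(d.values()))) for l, d in ap_per_label_phi.items()
    }
    label_recall = {
        l: float(np.mean(list(d.values()))) for l, d in recall_per_label_phi.items()
    }
    mAP = float(np.mean(list(label_ap.values())))
    mAR = float(np.mean(list(label_recall.values())))
    per_label = {
        l: {"AP": label_ap[l], "AR": label_recall[l]} for l in label_ap
    }
    return SettingMetrics(
        mAP=mAP,
        mAR=mAR,
        f1=_harmonic(mAP, mAR),
        per_label=per_label,
        counts=counts_out,
        ap_mode="score_ranked" if have_scores else "set_level",
    )


def evaluate_dataset(
    image_pairs: Sequence[Tuple[Sequence[InstanceMask], Sequence[InstanceMask]]],
    presets: Dict[str, Tuple[float, ...]] = PRESETS,
    strict_coco: bool = False,
) -> EvalReport:
    """Evaluate (predictions, ground-truth) pairs across all preset
    threshold settings."""
    evals = [
        match_predictions(preds, gts, strict_coco=strict_coco)
        for preds, gts in image_pairs
    ]
    settings = {
        name: compute_metrics(
            evals, EvalConfig(thresholds=ths, strict_coco=strict_coco), name
        )
        for name, ths in presets.items()
    }
    return EvalReport(
        settings=settings,
        n_images=len(image_pairs),
        n_dropped_empty=sum(ev.n_dropped_empty for ev in evals),
    )


# ---------------------------------------------------------------------------
# Scalar helpers
# ---------------------------------------------------------------------------

def simple_accuracy(n_correct: int, n_total: int) -> float:
    """Plain accuracy — reported only as a diagnostic, because with heavily
    imbalanced classes (e.g. nine capillaries and one cardiomyocyte) it
    hides a total failure on the rare class."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_correct <= n_total):
        raise ValueError("n_correct must lie in [0, n_total]")
    return n_correct / n_total


def relative_error(predicted: float, truth: float) -> float:
    """delta = |predicted - truth| / truth; undefined at truth == 0."""
    if truth == 0:
        raise ZeroDivisionError("relative error undefined for zero truth")
    return abs(predicted - truth) / truth


def aggregate_runs(values: Sequence[float]) -> Tuple[float, float]:
    """Sample mean and sample SD (n-1 denominator) over >= 2 runs."""
    if len(values) < 2:
        raise ValueError("need at least two runs to aggregate")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))
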