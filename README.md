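# capquant

Weakly supervised instance segmentation and capillarization
quantification for basement-membrane-immunostained myocardium.

## What it does and for whom

Cardiac capillary rarefaction is quantified from immunostained myocardial
cross-sections. Staining a single basement-membrane protein (collagen IV)
outlines cardiomyocytes (CM) and capillaries (CAP) at once — both appear
as dark interiors enclosed by bright membrane ridges — but identifying
and segmenting every instance by hand is slow and requires expertise.
`capquant` is for cardiovascular imaging labs that want that analysis
automated with only weak (bounding-box) training annotations.

The core idea is prompt engineering for dense scenes. An object detector
supplies one labelled bounding box `B_i` per structure. Because CM
profiles are non-convex, CM boxes overlap and capillary boxes often lie
wholly inside a CM box, so a box prompt alone under-determines the
target. Each detection is therefore expanded into an *enhanced prompt*
for a promptable segmentation backend:

* `B_i` — coarse constraint, the maximal extent of the mask;
* `P_i = {(c_j, 1{j=i})}` — fine constraint: every detection centroid
  `c_j` falling inside `B_i`, labelled 1 for the target itself and 0 for
  intruding neighbours (an O(n²) traversal over the n detections).

From the predicted masks the package derives the standard
capillarization measurements per field of view (FOV): CM and capillary
counts, total areas (µm²), CDFA = n_cap / FOV area (µm⁻²), CDCA =
n_cap / CM area (µm⁻²), and CCR = n_cap / n_cm. Evaluation uses
IoU-thresholded outcome classification with mAP / mAR / F1 at φ = 0.5,
0.75 and the [0.5:0.95] sweep, aggregated over repeated runs as
mean ± SD.

The detector and the promptable segmenter are pluggable contracts. The
built-in oracle detector (ground-truth boxes, optionally jittered) and a
deterministic reference segmenter (Otsu-threshold dark-component
selection honouring positive/negative points) close the loop so the
entire pipeline runs, and is tested, without any trained weights; slots
for a YOLO-family detector and a pretrained Segment Anything backend
accept real models when available. A seeded synthetic-scene generator
reproduces the dense-packing phenomena for testing.

## Worked example

```python
from capquant import (
    PipelineConfig, assess, evaluate_dataset, generate_scene, predict,
    report_errors, scene_statistics,
)
from capquant.synth import easy_scene_spec, _meta_for

spec = easy_scene_spec(seed=1, size=256)        # 256 px, ~21.25 um FOV
image, gt = generate_scene(spec)
print(scene_statistics(gt))

config = PipelineConfig(meta=_meta_for(256))
detections, prompts, result = predict(image, config, annotations=gt)
print(evaluate_dataset([(result.instances, gt)]).summary()["iou_0.50"])

pred_report = assess(result.valid_instances(), config.meta)
print(pred_report.as_dict())
print(report_errors(pred_report, assess(list(gt), config.meta)))
```

prints

```
{'n_cm': 6, 'n_cap': 12, 'cap_enclosed_fraction': 0.5, 'cm_box_overlap_rate': 0.533...}
{'mAP': 1.0, 'mAR': 1.0, 'F1': 1.0}
{'n_cm': 6, 'n_cap': 12, 'area_cm_um2': 423.649..., 'area_cap_um2': 3.224...,
 'cdfa_per_um2': 0.026574..., 'cdca_per_um2': 0.028325..., 'ccr': 2.0}
{'n_cm': 0.0, 'n_cap': 0.0, 'area_cm_um2': 3.25e-05, ..., 'ccr': 0.0}
```

Reading it: the generated scene has 6 CMs and 12 capillaries, half the
capillary boxes enclosed by a CM box and 53 % of CM box pairs
overlapping — the regime where fine constraints matter. The oracle
detector plus reference segmenter recover every instance (mAP = mAR =
F1 = 1 at IoU 0.5 on this noise-free preset), the predicted
capillarization report shows 2 capillaries per CM (CCR = 2.0) at a
capillary density of 0.0266 µm⁻² of FOV, and every relative error δ
against the ground-truth report is at (or within 10⁻⁴ of) zero.

A `capquant` console script exposes the stages
(`synth | preprocess | annotate | split | augment | predict | assess |
evaluate | benchmark`); run `capquant --help`.

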