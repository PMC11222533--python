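# Methods

## The problem

Cardiac capillary rarefaction — a drop in myocardial capillary density —
accompanies many heart disorders, and is usually quantified from
immunostained tissue cross-sections. Staining a single basement-membrane
protein (collagen IV) outlines cardiomyocytes (CM) and capillaries (CAP)
simultaneously: both structure classes appear as dark interiors enclosed
by bright membrane ridges in a single-channel fluorescence image. The
analysis burden then shifts entirely to image analysis: every CM profile
and capillary ring in the field of view must be identified, classified
and segmented before density measurements can be computed.

`capquant` automates this with a weakly supervised two-block design. A
detector (trainable from bounding-box annotations only) finds and
classifies objects; an engineered prompt per detection then drives a
promptable segmentation backend, zero-shot, to produce pixel-accurate
instance masks; capillarization measurements are derived from the masks.

## Enhanced prompts for dense scenes

Myocardial cross-sections are densely tessellated: CM profiles are
non-convex, so the bounding boxes of adjacent CMs overlap, and capillary
boxes frequently lie entirely inside a CM box. A box prompt alone is then
ambiguous — several structures occupy the same box. Each detection `i`
therefore receives an *enhanced* prompt:

* **coarse constraint** — the bounding box `B_i`, defining the maximal
  extent of the predicted mask (enforced by clipping for every backend);
* **fine constraint** — a binary-labelled point set `P_i`: the centroids
  `c_j` of *all* detections are traversed, and those falling inside `B_i`
  (half-open membership) are kept, labelled 1 for `j = i` and 0
  otherwise. The positive point marks the target, the negative points
  mark intruding neighbours.

Centroids are geometric box centres, not mask centres of mass: at
inference time only boxes exist. The traversal is the literal O(n²)
double loop; scenes carry tens of objects, so no acceleration is
warranted, and the test suite holds the implementation to exact
equivalence with an independently coded double loop up to n = 50.

Boundary behaviour is fixed by the half-open convention (inclusive lower
edge, exclusive upper edge): a centroid lying exactly on a box's upper
edge is *not* a member. This is a deterministic tie-break chosen for
consistency with 0-based raster indexing; either convention is defensible
and the choice only matters on exact-tie geometry.

## Detector and segmenter contracts

Neither neural component is re-implemented; both are adapter slots.

* The **oracle detector** derives one detection per ground-truth mask
  (tight box, true label, confidence 1). An optional seeded uniform
  jitter of ±j px per box edge emulates an imperfect detector. This
  closes the loop for testing without weights or a GPU. A `yolo` adapter
  slot accepts a trained model when the optional dependency is present.
* The **reference prompt segmenter** is a deterministic classical
  backend exploiting the stated staining polarity (dark interiors, bright
  ridges): Otsu threshold inside the box crop, dark-side foreground,
  4-connected components; the component under the positive point is the
  prediction, and any component containing a negative point is deleted —
  including the candidate itself, in which case the prediction is flagged
  failed (an empty mask, never an exception). 4-connectivity is chosen so
  one-pixel diagonal touches across a thinned ridge do not merge
  neighbouring interiors. A `sam` backend slot exists for the pretrained
  Segment Anything model but ships no weights; one mask is emitted per
  prompt (any multi-proposal ambiguity resolution is the backend's
  concern).

## Synthetic scenes

The generator produces the study conditions for all closed-loop tests.
A frame is partitioned by nearest-seed assignment where each seed's
distance field is perturbed by a smooth Gaussian-filtered noise field;
`shape_irregularity` (0–1) scales the perturbation, morphing convex
Voronoi cells into lobed non-convex CM profiles. CM ground truth is the
region eroded by the membrane thickness. Capillaries are stamped at
tessellation boundary/junction points — where capillaries sit in real
myocardium — as a dark lumen disk (the CAP ground truth) inside a bright
ring carved out of the host CM. Rendering uses interior level 6000 and
ridge level 45000 counts (16-bit), Gaussian blur σ = 0.6 px, and optional
additive Gaussian noise.

Defaults mirror the acquisition geometry of confocal basement-membrane
imaging: 512×512 px, 42.5 µm × 42.5 µm FOV, 16-bit; membrane thickness
3 px and lumen radii 5–9 px at that scale (scaled proportionally at other
frame sizes, with a 3-px floor). Two presets matter:

* `default` — n_cm = 6, ~2 capillaries per CM, irregularity 0.6, noise SD
  1500 counts: reproduces the dense-packing phenomena (overlapping CM
  boxes; CAP boxes enclosed by CM boxes).
* `easy` — irregularity 0.2, no noise: the closed-loop benchmark
  condition.

What the generator does **not** emulate: photon noise statistics, point
spread, autofluorescence, staining heterogeneity, out-of-focus light, or
structures without clear edges. Passing closed-loop tests therefore
demonstrates the correctness of the prompting, segmentation-contract,
evaluation and measurement machinery — not expected performance on real
micrographs, where a trained detector and a pretrained promptable
segmenter take the two contract slots.

Closed-loop runs in the test suite and the acceptance script use 192 px
frames (FOV scaled to ~15.9 µm) with 6 CMs and 3 scenes × 5 runs — sizes
chosen so a full run completes in seconds while still exercising every
dense-packing phenomenon.

## Dataset tools

* **Preprocessing**: 3×3 Wiener filter, then a linear percentile stretch
  (0.35 % / 99.65 % clipping — a conventional robust-contrast choice) to
  the full 16-bit range. A constant frame maps to zeros.
* **Splits**: seeded shuffle; test = round-half-up(0.30·n), validation =
  round-half-up(0.10·(n − test)), remainder train. Round-half-up is the
  rule that yields the canonical 107 → 67/8/32 partition.
* **Rotation augmentation** emits all three fixed directions (90° cw,
  90° ccw, 180°) per image — a deterministic superset of a random
  choice; a seeded `target_total` subsample supports fixed augmented-set
  sizes.
* **Mosaic augmentation** downscales four images by 2 (mean pooling;
  any-foreground pooling for masks, so 1-px-thin features survive) into
  the four quadrants, with a seeded quadrant permutation. The matching
  floor/ceil box transform makes bbox-of-transformed-mask equal
  transformed-bbox exactly.
* **ROI admission**: a field of view qualifies when ≥ 80 % of it is
  covered by annotated myocardial structures.
* Weak annotations are tight boxes circumscribing the manual masks,
  written as YOLO-txt (half-pixel round-trip at 6 decimals) or COCO JSON
  (bit-exact via uncompressed column-major RLE).

## Evaluation

A predicted/ground-truth pair at IoU threshold φ is classified by the
four-way rule: same label → TP if IoU ≥ φ else FP; different label → TN
if IoU ≥ φ else FN. This is deliberately not the strict COCO convention
(where a label mismatch simply fails to match); a `strict_coco` flag
restores that behaviour for comparability. Matching — left open by the
rule itself — is one-to-one, greedy by descending IoU, label-agnostic;
unmatched predictions are FP, unmatched ground truths FN; empty (failed)
predictions are dropped before matching and surface as FN through their
unmatched ground truths. Greedy matching equals the optimal (Hungarian)
assignment whenever IoU structure is unambiguous; the test suite measures
and bounds the divergence rate rather than assuming it is zero.

Precision and recall use TP/FP/FN only; TN is tallied and reported.
Average precision integrates the score-ranked precision–recall curve
(COCO 101-point interpolation) when confidence scores exist, else the
set-level operating-point precision is used and flagged in `ap_mode`.
mAP/mAR average over the two labels; the `[0.5:0.95]` setting averages
additionally over the ten thresholds (step 0.05); F1 is the harmonic mean
of mAP and mAR. Runs aggregate as sample mean ± SD (n − 1 denominator);
the benchmark protocol defaults to five runs. Plain accuracy exists only
as a diagnostic: with nine capillaries and one CM, missing the CM still
scores 90 %, which is why it is excluded from headline metrics.

## Capillarization measurements

Per image, from labelled instance masks: n_cm, n_cap, total CM area and
total CAP area (µm², pixel count × pixel area), CDFA = n_cap / FOV area
(µm⁻²), CDCA = n_cap / CM area (µm⁻²), CCR = n_cap / n_cm. Three
identities hold exactly by construction and are asserted property-style:
CDFA·FOV = n_cap, CDCA·CM-area = n_cap, CCR·n_cm = n_cap. CDCA and CCR
are undefined (explicit `None`, never zero) when their denominators
vanish. Areas default to per-mask summation — overlapping predictions
each count — with a union-footprint mode behind `area_mode="union"`;
assessment error is the relative error δ = |predicted − truth| / truth,
skipped with a flag when the truth is zero or undefined.

## Numerical and degenerate-input choices

* Boxes are half-open, 0-based, float-valued; area = width·height exactly.
* `bbox_from_mask` on an empty mask raises; it never returns a degenerate
  box. IoU of two empty masks is an error, not 0.
* Otsu on a zero-range crop cannot threshold; the reference segmenter
  returns a failed prediction there.
* Box jitter clips to image bounds and preserves a ≥ 1 px extent.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit spec/config fields; identical seeds reproduce rasters bit for
  bit.

## Known limitations

* The reference segmenter depends on the bright-ridge/dark-interior
  polarity and a bimodal intensity histogram inside each box; it is a
  contract-filling backend, not a competitor to a pretrained promptable
  model on real data.
* The four-way outcome rule double-books nothing but departs from COCO;
  numbers under it are not directly comparable to COCO-tool outputs
  unless `strict_coco` is enabled.
* Greedy matching can diverge from the optimal assignment on ambiguous
  overlap structure; divergences are measurable via the test oracle.
* Whether a detection's centroid that lies exactly on a neighbouring
  box's edge belongs to that neighbour's prompt is convention-defined
  (half-open rule) — behaviour on exact ties is deterministic but
  arbitrary.
* No 3-D (Z-stack) support, no multi-channel handling, no stain
  normalization.
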