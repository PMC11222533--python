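"""Annotation and image serialization: COCO JSON, YOLO-txt, index TIFF.

COCO segmentations are written as uncompressed column-major run-length
encodings (the ``{"size": [h, w], "counts": [...]}`` form) so that mask
round-trips are bit-exact; polygon segmentations are accepted on read and
rasterized with scikit-image. Boxes round-trip bit-exactly through COCO
``[x, y, w, h]``; YOLO-txt normalized boxes round-trip to within the
quantization of their fixed-precision text encoding (half a pixel at
6 decimals).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import tifffile
from skimage.draw import polygon as draw_polygon

from .geometry import (
    BoundingBox,
    ClassLabel,
    ImageMeta,
    InstanceMask,
    bbox_from_mask,
)

CATEGORY_IDS: Dict[ClassLabel, int] = {ClassLabel.CM: 1, ClassLabel.CAP: 2}
CATEGORY_NAMES: Dict[int, ClassLabel] = {v: k for k, v in CATEGORY_IDS.items()}

COCO_CATEGORIES = [
    {"id": 1, "name": "CM", "supercategory": "structure"},
    {"id": 2, "name": "CAP", "supercategory": "structure"},
]


# ---------------------------------------------------------------------------
# Run-length encoding (COCO convention: column-major, starts with zeros run)
# ---------------------------------------------------------------------------

def rle_encode(raster: np.ndarray) -> Dict:
    """Encode a binary raster as an uncompressed COCO RLE object."""
    raster = np.asarray(raster, dtype=bool)
    h, w = raster.shape
    flat = raster.flatten(order="F").astype(np.int8)
    # runs of constant value; COCO counts always start with a zeros run
    change = np.flatnonzero(np.diff(flat))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [flat.size]))
    counts = (ends - starts).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    if flat.size == 0:
        counts = []
    return {"size": [h, w], "counts": counts}


def rle_decode(rle: Dict) -> np.ndarray:
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def polygon_to_raster(coords: Sequence[float], shape: Tuple[int, int]) -> np.ndarray:
    """Rasterize one COCO polygon (flat [x0, y0, x1, y1, ...] list)."""
    xs = np.asarray(coords[0::2], dtype=float)
    ys = np.asarray(coords[1::2], dtype=float)
    rr, cc = draw_polygon(ys, xs, shape=shape)
    raster = np.zeros(shape, dtype=bool)
    raster[rr, cc] = True
    return raster


# ---------------------------------------------------------------------------
# COCO instance annotations
# ---------------------------------------------------------------------------

def masks_to_coco(
    masks_per_image: Dict[int, List[InstanceMask]],
    meta: ImageMeta,
    file_names: Optional[Dict[int, str]] = None,
) -> Dict:
    """Build a COCO dataset dict from per-image instance masks."""
    images = []
    annotations = []
    ann_id = 1
    for image_id in sorted(masks_per_image):
        name = (file_names or {}).get(image_id, f"image_{image_id:04d}.tif")
        images.append(
            {
                "id": image_id,
                "file_name": name,
                "width": meta.width_px,
                "height": meta.height_px,
            }
        )
        for mask in masks_per_image[image_id]:
            box = bbox_from_mask(mask)
            ann = {
                "id": ann_id,
                "image_id": image_id,
                "category_id": CATEGORY_IDS[mask.label],
                "segmentation": rle_encode(mask.raster),
                "area": float(mask.pixel_count),
                "bbox": list(box.as_xywh()),
                "iscrowd": 0,
            }
            if mask.score is not None:
                ann["score"] = float(mask.score)
            annotations.append(ann)
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": COCO_CATEGORIES,
    }


def coco_to_masks(coco: Dict) -> Dict[int, List[InstanceMask]]:
    """Read COCO instance annotations (RLE or polygon) back into masks."""
    dims = {im["id"]: (im["height"], im["width"]) for im in coco["images"]}
    out: Dict[int, List[InstanceMask]] = {im["id"]: [] for im in coco["images"]}
    for ann in coco["annotations"]:
        shape = dims[ann["image_id"]]
        seg = ann["segmentation"]
        if isinstance(seg, dict):
            raster = rle_decode(seg)
        else:  # list of polygons
            raster = np.zeros(shape, dtype=bool)
            for poly in seg:
                raster |= polygon_to_raster(poly, shape)
        label = CATEGORY_NAMES[ann["category_id"]]
        out[ann["image_id"]].append(
            InstanceMask(raster, label, score=ann.get("score"))
        )
    return out


def detections_to_coco_records(detections, image_id: int = 1) -> List[Dict]:
    """COCO detection-result records ([{image_id, category_id, bbox, score}])."""
    return [
        {
            "image_id": image_id,
            "category_id": CATEGORY_IDS[d.label],
            "bbox": list(d.box.as_xywh()),
            "score": float(d.confidence),
        }
        for d in detections
    ]


def coco_records_to_detections(records: Sequence[Dict]):
    from .detection import Detection  # local import avoids a cycle

    return [
        Detection(
            box=BoundingBox.from_xywh(*r["bbox"]),
            label=CATEGORY_NAMES[r["category_id"]],
            confidence=float(r.get("score", 1.0)),
        )
        for r in records
    ]


# ---------------------------------------------------------------------------
# YOLO-txt (class cx cy w h, all normalized to image extent)
# ---------------------------------------------------------------------------

YOLO_CLASS_IDS: Dict[ClassLabel, int] = {ClassLabel.CM: 0, ClassLabel.CAP: 1}
YOLO_CLASS_NAMES: Dict[int, ClassLabel] = {v: k for k, v in YOLO_CLASS_IDS.items()}


def boxes_to_yolo_lines(
    boxes: Sequence[BoundingBox],
    labels: Sequence[ClassLabel],
    meta: ImageMeta,
) -> List[str]:
    lines = []
    for box, label in zip(boxes, labels):
        cx = (box.x_min + box.x_max) / 2.0 / meta.width_px
        cy = (box.y_min + box.y_max) / 2.0 / meta.height_px
        w = box.width / meta.width_px
        h = box.height / meta.height_px
        lines.append(
            f"{YOLO_CLASS_IDS[label]} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
        )
    return lines


def yolo_lines_to_boxes(
    lines: Sequence[str], meta: ImageMeta
) -> Tuple[List[BoundingBox], List[ClassLabel]]:
    boxes, labels = [], []
    for line in lines:
        line = line.strip()
        if not line:
            continue
        cls, cx, cy, w, h = line.split()
        cx, cy, w, h = (float(v) for v in (cx, cy, w, h))
        x_min = (cx - w / 2) * meta.width_px
        y_min = (cy - h / 2) * meta.height_px
        boxes.append(
            BoundingBox(x_min, y_min, x_min + w * meta.width_px, y_min + h * meta.height_px)
        )
        labels.append(YOLO_CLASS_NAMES[int(cls)])
    return boxes, labels


# ---------------------------------------------------------------------------
# Instance-index TIFF (uint16, 0 = background, k = instance k's pixels)
# ---------------------------------------------------------------------------

def masks_to_index_image(masks: Sequence[InstanceMask]) -> np.ndarray:
    if not masks:
        raise ValueError("no masks to index")
    if len(masks) > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for a 16-bit index image")
    index = np.zeros(masks[0].raster.shape, dtype=np.uint16)
    for k, mask in enumerate(masks, start=1):
        index[mask.raster] = k  # later instances win overlaps
    return index


def index_image_to_masks(
    index: np.ndarray, labels: Sequence[ClassLabel]
) -> List[InstanceMask]:
    out = []
    for k, label in enumerate(labels, start=1):
        out.append(InstanceMask(index == k, label))
    return out


def write_index_tiff(path: str | Path, masks: Sequence[InstanceMask]) -> None:
    tifffile.imwrite(str(path), masks_to_index_image(masks))
    labels = [m.label.value for m in masks]
    Path(str(path) + ".labels.json").write_text(json.dumps(labels))


def read_index_tiff(path: str | Path) -> List[InstanceMask]:
    index = tifffile.imread(str(path))
    labels = [
        ClassLabel(v)
        for v in json.loads(Path(str(path) + ".labels.json").read_text())
    ]
    return index_image_to_masks(index, labels)


# ---------------------------------------------------------------------------
# Images and small JSON helpers
# ---------------------------------------------------------------------------

def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), image)


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(str(path))
    import imageio.v3 as iio

    return iio.imread(str(path))


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
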