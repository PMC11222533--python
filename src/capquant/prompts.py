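"""Prompt engineering for dense scenes: boxes plus binary-labelled centroids.

This is the heart of the method. In myocardial cross-sections,
cardiomyocyte profiles are non-convex and tightly tessellated, so their
bounding boxes overlap heavily and capillary boxes often sit entirely
inside a cardiomyocyte box. A box prompt alone then under-determines the
target. Each detection's prompt is therefore *enhanced*: the box acts as a
coarse constraint (the maximal extent of the mask) and a set of
binary-labelled centroids acts as a fine constraint — the target's own box
centroid labelled 1, and the centroid of every other detection that falls
inside the box labelled 0, telling a promptable segmenter which structure
in the box is the target and which are intruding neighbours.

Prompt generation traverses the centroids of all n detections for each of
the n boxes, so its worst-case cost is O(n^2); scenes hold tens of
objects, so no acceleration is needed or attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, NamedTuple, Sequence

from .geometry import BoundingBox, ClassLabel, Point2D, bbox_centroid, point_in_box


class LabeledPoint(NamedTuple):
    """A centroid with a binary prompt label (1 = target, 0 = neighbour)."""

    point: Point2D
    binary_label: int


@dataclass(frozen=True)
class PromptSet:
    """The enhanced prompt for one detection.

    Invariants: exactly one point carries label 1 and it is the centroid of
    ``box``; every point lies within ``box`` under the half-open rule.
    """

    box: BoundingBox
    points: tuple  # tuple[LabeledPoint, ...]
    label: ClassLabel
    source_index: int

    @property
    def positive_point(self) -> Point2D:
        for lp in self.points:
            if lp.binary_label == 1:
                return lp.point
        raise ValueError("prompt has no positive point")

    @property
    def negative_points(self) -> List[Point2D]:
        return [lp.point for lp in self.points if lp.binary_label == 0]


def generate_prompts(detections: Sequence) -> List[PromptSet]:
    """Build one enhanced prompt per detection.

    For detection i with box B_i: traverse the centroids c_j of *all*
    detections and keep those falling within B_i; c_i gets binary label 1,
    every other kept centroid gets 0. A box always contains its own
    centroid, so the positive point is always present (asserted, not
    assumed). An empty detection list yields an empty prompt list.
    """
    centroids = [bbox_centroid(d.box) for d in detections]
    prompts: List[PromptSet] = []
    for i, det in enumerate(detections):
        points = []
        for j, c_j in enumerate(centroids):
            if point_in_box(c_j, det.box):
                points.append(LabeledPoint(c_j, 1 if j == i else 0))
        assert any(lp.binary_label == 1 for lp in points), (
            "box does not contain its own centroid — invalid detection box"
        )
        prompts.append(
            PromptSet(
                box=det.box,
                points=tuple(points),
                label=det.label,
                source_index=i,
            )
        )
    return prompts


def prompt_to_json_obj(prompt: PromptSet) -> dict:
    """Exchange format between the prompt generator and any backend."""
    return {
        "box": list(prompt.box.as_tuple()),
        "points": [[lp.point.x, lp.point.y, lp.binary_label] for lp in prompt.points],
        "class": prompt.label.value,
        "source_index": prompt.source_index,
    }


def prompt_from_json_obj(obj: dict) -> PromptSet:
    return PromptSet(
        box=BoundingBox(*obj["box"]),
        points=tuple(
            LabeledPoint(Point2D(x, y), int(lbl)) for x, y, lbl in obj["points"]
        ),
        label=ClassLabel(obj["class"]),
        source_index=int(obj.get("source_index", -1)),
    )


def prompts_to_json(prompts: Sequence[PromptSet]) -> str:
    return json.dumps([prompt_to_json_obj(p) for p in prompts])


def prompts_from_json(text: str) -> List[PromptSet]:
    return [prompt_from_json_obj(o) for o in json.loads(text)]
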