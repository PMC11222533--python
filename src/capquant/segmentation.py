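"""Prompt-driven segmentation backends.

The segmentation stage is a contract: given an image and a list of
enhanced prompts, return exactly one mask per prompt, with every
foreground pixel inside the prompt's box (the box is defined as the
*maximum range* of the mask, so containment is enforced by clipping for
every backend). Two backends are registered:

``reference``
    A deterministic classical segmenter that exploits the stated staining
    polarity — basement-membrane immunostains render bright ridges around
    dark object interiors. It thresholds the box crop with Otsu, takes the
    connected dark component under the positive point, and discards any
    component touched by a negative point. No weights, no randomness; it
    makes the whole pipeline runnable and testable offline.

``sam``
    A slot for the pretrained promptable Segment Anything model (zero-shot
    via the same prompt interface). It carries no weights here and raises
    with instructions if selected without the optional dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .geometry import InstanceMask
from .prompts import PromptSet


@dataclass
class SegmentationResult:
    """One mask per input prompt, in prompt order.

    Failed predictions (the positive point hit no component) are empty
    masks, kept in place so indices stay parallel to the prompts.
    """

    instances: List[InstanceMask]
    prompt_indices: List[int]

    @property
    def n_failed(self) -> int:
        return sum(1 for m in self.instances if m.is_empty)

    def valid_instances(self) -> List[InstanceMask]:
        return [m for m in self.instances if not m.is_empty]


BackendFn = Callable[[np.ndarray, PromptSet], np.ndarray]

_BACKENDS: Dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def available_backends() -> List[str]:
    return sorted(_BACKENDS)


def _box_slices(prompt: PromptSet, shape) -> tuple:
    h, w = shape[:2]
    x0 = max(int(np.floor(prompt.box.x_min)), 0)
    y0 = max(int(np.floor(prompt.box.y_min)), 0)
    x1 = min(int(np.ceil(prompt.box.x_max)), w)
    y1 = min(int(np.ceil(prompt.box.y_max)), h)
    return slice(y0, y1), slice(x0, x1)


def segment_with_prompts(
    image: np.ndarray,
    prompts: Sequence[PromptSet],
    backend: str = "reference",
) -> SegmentationResult:
    """Run a backend over all prompts; clip every mask to its prompt box."""
    if backend not in _BACKENDS:
        raise KeyError(
            f"unknown segmentation backend {backend!r}; "
            f"registered: {available_backends()}"
        )
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    fn = _BACKENDS[backend]
    instances: List[InstanceMask] = []
    for i, prompt in enumerate(prompts):
        raster = np.asarray(fn(image, prompt), dtype=bool)
        if raster.shape != image.shape:
            raise ValueError(
                f"backend {backend!r} returned shape {raster.shape}, "
                f"expected {image.shape}"
            )
        clipped = np.zeros_like(raster)
        ys, xs = _box_slices(prompt, image.shape)
        clipped[ys, xs] = raster[ys, xs]
        instances.append(InstanceMask(clipped, prompt.label))
    return SegmentationResult(
        instances=instances, prompt_indices=[i for i in range(len(prompts))]
    )


def reference_prompt_segmenter(image: np.ndarray, prompt: PromptSet) -> np.ndarray:
    """Deterministic dark-interior segmenter for membrane-outlined objects.

    Within the box crop: Otsu-threshold, keep pixels *below* the threshold
    (dark interiors bounded by bright ridges), 4-connected components; the
    component under the positive point is the candidate, and any component
    containing a negative point is deleted — including the candidate, in
    which case the prediction fails (empty mask, not an exception).
    """
    ys, xs = _box_slices(prompt, image.shape)
    crop = np.asarray(image[ys, xs], dtype=np.float64)
    out = np.zeros(image.shape, dtype=bool)
    if crop.size == 0 or np.ptp(crop) == 0:
        return out  # structureless crop: failed prediction
    th = threshold_otsu(crop)
    fg = crop < th
    comps = cc_label(fg, connectivity=1)

    def comp_at(pt) -> int:
        r = int(np.floor(pt.y)) - ys.start
        c = int(np.floor(pt.x)) - xs.start
        if 0 <= r < comps.shape[0] and 0 <= c < comps.shape[1]:
            return int(comps[r, c])
        return 0

    target = comp_at(prompt.positive_point)
    if target == 0:
        return out  # positive point on no dark component: failed
    banned = {comp_at(p) for p in prompt.negative_points}
    if target in banned:
        return out
    out[ys, xs] = comps == target
    return out


register_backend("reference", reference_prompt_segmenter)


def _sam_backend(image: np.ndarray, prompt: PromptSet) -> np.ndarray:
    try:
        import segment_anything  # type: ignore  # noqa: F401
    except ImportError as exc:
        raise RuntimeError(
            "the 'sam' backend needs the optional segment-anything package "
            "and a pretrained checkpoint; install them and use "
            "capquant.segmentation.register_backend to bind a predictor"
        ) from exc
    raise RuntimeError(  # pragma: no cover
        "no SAM checkpoint is bundled; bind a configured predictor via "
        "register_backend('sam', fn)"
    )


register_backend("sam", _sam_backend)
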