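"""Preprocessing, splitting, augmentation and weak annotation."""

import numpy as np
import pytest

from capquant.dataset import (
    AugmentationConfig,
    SplitSpec,
    downscale_box,
    expand_training_set,
    masks_to_detector_annotations,
    mosaic_augment,
    mosaic_box,
    passes_roi_criterion,
    preprocess,
    rotate_augment,
    rotate_box,
    split_dataset,
    structure_coverage,
)
from capquant.geometry import (
    ClassLabel,
    EmptyMaskError,
    ImageMeta,
    InstanceMask,
    bbox_from_mask,
)
from capquant.io import (
    boxes_to_yolo_lines,
    yolo_lines_to_boxes,
)

from conftest import block_mask, make_mask


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        img = np.full((32, 32), 7000, dtype=np.uint16)
        assert not preprocess(img).any()

    def test_impulse_noise_variance_reduced(self):
        # sparse full-scale impulses on a dark background; compare variance
        # on the range-normalized scale (min-max stretch on both sides)
        rng = np.random.default_rng(0)
        img = np.zeros((64, 64), dtype=np.uint16)
        spikes = rng.random((64, 64)) < 0.05
        img[spikes] = 65535
        out = preprocess(img, clip_percentiles=(0.0, 100.0)).astype(float)
        var_in = np.var(img.astype(float) / 65535.0)
        var_out = np.var(out / 65535.0)
        assert var_out < var_in

    def test_ramp_ordering_preserved(self):
        ramp = np.tile(np.linspace(0, 65535, 64, dtype=np.uint16), (64, 1))
        out = preprocess(ramp)
        interior = out[2:-2, 2:-2]
        assert (np.diff(interior.astype(int), axis=1) >= 0).all()

    def test_rejects_non_2d(self):
        with pytest.raises(ValueError):
            preprocess(np.zeros((4, 4, 3), dtype=np.uint16))


class TestSplit:
    def test_canonical_107_partition(self):
        train, val, test = split_dataset(107, SplitSpec(seed=0))
        assert (len(train), len(val), len(test)) == (67, 8, 32)

    def test_small_n_round_half_up(self):
        train, val, test = split_dataset(10, SplitSpec(seed=1))
        assert (len(train), len(val), len(test)) == (6, 1, 3)

    def test_deterministic_under_seed(self):
        assert split_dataset(50, SplitSpec(seed=9)) == split_dataset(
            50, SplitSpec(seed=9)
        )
        assert split_dataset(50, SplitSpec(seed=9)) != split_dataset(
            50, SplitSpec(seed=10)
        )

    @pytest.mark.parametrize("n", [10, 17, 107, 333])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_disjoint_and_exhaustive(self, n, seed):
        train, val, test = split_dataset(n, SplitSpec(seed=seed))
        combined = sorted(train + val + test)
        assert combined == list(range(n))

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2, SplitSpec())


class TestRotation:
    def test_single_pixel_cw90(self):
        img = np.zeros((4, 4), dtype=np.uint16)
        m = make_mask((4, 4), [(0, 0)])  # pixel at x=0, y=0
        rotated = dict(
            (name, masks) for name, _, masks in rotate_augment(img, [m])
        )
        assert bbox_from_mask(rotated["cw90"][0]).as_tuple() == (3, 0, 4, 1)
        assert bbox_from_mask(rotated["ccw90"][0]).as_tuple() == (0, 3, 1, 4)
        assert bbox_from_mask(rotated["rot180"][0]).as_tuple() == (3, 3, 4, 4)

    def test_rot180_is_involution(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 65535, (16, 16), dtype=np.uint16)
        m = InstanceMask(rng.random((16, 16)) > 0.7, ClassLabel.CM)
        _, img180, (m180,) = rotate_augment(img, [m])[2]
        _, img360, (m360,) = rotate_augment(img180, [m180])[2]
        assert np.array_equal(img360, img)
        assert np.array_equal(m360.raster, m.raster)

    def test_area_preserved_and_box_commutes(self):
        rng = np.random.default_rng(3)
        raster = rng.random((20, 20)) > 0.8
        raster[4, 7] = True
        m = InstanceMask(raster, ClassLabel.CAP)
        img = np.zeros((20, 20), dtype=np.uint16)
        for name, _, (rm,) in rotate_augment(img, [m]):
            assert rm.pixel_count == m.pixel_count
            assert bbox_from_mask(rm).as_tuple() == rotate_box(
                bbox_from_mask(m), name, 20
            ).as_tuple()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            rotate_augment(np.zeros((4, 6), np.uint16), [])


class TestMosaic:
    @staticmethod
    def _sample(seed, size=32):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 65535, (size, size), dtype=np.uint16)
        masks = [
            block_mask((size, size), 2, 10, 3, 12, ClassLabel.CM),
            block_mask((size, size), 15, 22, 18, 27, ClassLabel.CAP),
        ]
        return img, masks

    def test_annotation_count_conserved(self):
        samples = [self._sample(s) for s in range(4)]
        out_img, out_masks = mosaic_augment(samples, seed=0)
        assert out_img.shape == (32, 32)
        assert len(out_masks) == sum(len(m) for _, m in samples)

    def test_full_frame_box_lands_in_one_quadrant(self):
        size = 32
        img = np.zeros((size, size), dtype=np.uint16)
        full = block_mask((size, size), 0, size, 0, size, ClassLabel.CM)
        out_img, out_masks = mosaic_augment([(img, [full])] * 4, seed=1)
        for m in out_masks:
            box = bbox_from_mask(m)
            assert (box.width, box.height) == (16, 16)
            assert box.x_min in (0, 16) and box.y_min in (0, 16)

    def test_box_transform_commutes_with_mask_transform(self):
        # the mosaic of four identical samples puts sample k's masks in
        # known quadrants; compare direct box halving against mask bbox
        img, masks = self._sample(7)
        out_img, out_masks = mosaic_augment([(img, masks)] * 4, seed=3)
        expected = set()
        for quadrant in range(4):
            for m in masks:
                expected.add(
                    mosaic_box(bbox_from_mask(m), quadrant, 32).as_tuple()
                )
        got = {bbox_from_mask(m).as_tuple() for m in out_masks}
        assert got == expected

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError):
            mosaic_augment([self._sample(0)] * 3)


class TestAnnotationsAndRoi:
    def test_records_have_tight_boxes(self):
        masks = [block_mask((16, 16), 1, 5, 2, 9, ClassLabel.CM) for _ in range(5)]
        records = masks_to_detector_annotations(masks)
        assert len(records) == 5
        assert records[0]["box"].as_tuple() == (2, 1, 9, 5)

    def test_empty_mask_rejected(self):
        empty = InstanceMask(np.zeros((8, 8), bool), ClassLabel.CAP)
        with pytest.raises(EmptyMaskError):
            masks_to_detector_annotations([empty])

    def test_yolo_round_trip_within_half_pixel(self):
        meta = ImageMeta(width_px=512, height_px=512)
        masks = [
            block_mask((512, 512), 37, 220, 41, 333, ClassLabel.CM),
            block_mask((512, 512), 400, 431, 77, 99, ClassLabel.CAP),
        ]
        boxes = [bbox_from_mask(m) for m in masks]
        labels = [m.label for m in masks]
        back, back_labels = yolo_lines_to_boxes(
            boxes_to_yolo_lines(boxes, labels, meta), meta
        )
        assert back_labels == labels
        for a, b in zip(boxes, back):
            assert np.allclose(a.as_tuple(), b.as_tuple(), atol=0.5)

    def test_roi_criterion(self, meta32):
        sparse = [block_mask((32, 32), 0, 8, 0, 8, ClassLabel.CM)]
        dense = [block_mask((32, 32), 0, 30, 0, 30, ClassLabel.CM)]
        assert structure_coverage(sparse, meta32) == pytest.approx(64 / 1024)
        assert not passes_roi_criterion(sparse, meta32)
        assert passes_roi_criterion(dense, meta32)


def test_expand_training_set_counts_and_target_total():
    rng = np.random.default_rng(0)
    samples = []
    for s in range(4):
        img = rng.integers(0, 65535, (32, 32), dtype=np.uint16)
        samples.append((img, [block_mask((32, 32), 4, 20, 6, 24, ClassLabel.CM)]))
    pool = expand_training_set(samples, AugmentationConfig(seed=0))
    # 4 originals + 12 rotations + 1 mosaic
    assert len(pool) == 17
    capped = expand_training_set(
        samples, AugmentationConfig(seed=0, target_total=10)
    )
    assert len(capped) == 10
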