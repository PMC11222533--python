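"""Four-way outcome rule, greedy matching, metric sweeps, aggregation."""


import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capquant.evaluation import (
    PRESETS,
    SWEEP_50_95,
    EvalConfig,
    aggregate_runs,
    classify_outcome,
    compute_metrics,
    evaluate_dataset,
    greedy_match,
    match_predictions,
    outcome_counts,
    relative_error,
    simple_accuracy,
)
from capquant.geometry import ClassLabel, InstanceMask

from conftest import block_mask


class TestClassifyOutcome:
    def test_identical_same_label_is_tp(self):
        m = block_mask((8, 8), 1, 5, 1, 5, ClassLabel.CM)
        assert classify_outcome(m, m, 0.5) == "TP"

    def test_identical_different_label_is_tn(self):
        a = block_mask((8, 8), 1, 5, 1, 5, ClassLabel.CM)
        b = block_mask((8, 8), 1, 5, 1, 5, ClassLabel.CAP)
        assert classify_outcome(a, b, 0.5) == "TN"

    def test_low_iou_same_label_is_fp(self):
        a = block_mask((4, 4), 0, 2, 0, 2, ClassLabel.CAP)
        b = block_mask((4, 4), 0, 2, 1, 3, ClassLabel.CAP)  # IoU = 1/3
        assert classify_outcome(a, b, 0.5) == "FP"

    def test_low_iou_different_label_is_fn(self):
        a = block_mask((4, 4), 0, 2, 0, 2, ClassLabel.CAP)
        b = block_mask((4, 4), 0, 2, 1, 3, ClassLabel.CM)
        assert classify_outcome(a, b, 0.5) == "FN"

    @settings(max_examples=40, deadline=None)
    @given(
        st.integers(0, 2**31 - 1),
        st.sampled_from([0.25, 0.5, 0.75, 0.95]),
    )
    def test_exhaustive_and_mutually_exclusive(self, seed, phi):
        rng = np.random.default_rng(seed)
        shape = (12, 12)
        r0, c0 = rng.integers(0, 6, 2)
        r1, c1 = rng.integers(0, 6, 2)
        a = block_mask(shape, r0, r0 + 5, c0, c0 + 5, list(ClassLabel)[int(rng.integers(2))])
        b = block_mask(shape, r1, r1 + 5, c1, c1 + 5, list(ClassLabel)[int(rng.integers(2))])
        outcome = classify_outcome(a, b, phi)
        # exactly one of the four (label-match x IoU-side) cells fires
        from capquant.geometry import mask_iou

        same = a.label == b.label
        high = mask_iou(a, b) >= phi
        expected = {
            (True, True): "TP",
            (True, False): "FP",
            (False, True): "TN",
            (False, False): "FN",
        }[(same, high)]
        assert outcome == expected


class TestMatching:
    def test_perfect_predictions_all_tp(self):
        gts = [
            block_mask((16, 16), 0, 6, 0, 6, ClassLabel.CM, score=None),
            block_mask((16, 16), 8, 14, 8, 14, ClassLabel.CAP, score=None),
        ]
        preds = [
            block_mask((16, 16), 0, 6, 0, 6, ClassLabel.CM, score=1.0),
            block_mask((16, 16), 8, 14, 8, 14, ClassLabel.CAP, score=1.0),
        ]
        ev = match_predictions(preds, gts)
        for phi in (0.5, 0.75, 1.0):
            c = outcome_counts(ev, phi)
            assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_no_predictions_all_fn(self):
        gts = [block_mask((8, 8), 0, 4, 0, 4, ClassLabel.CM) for _ in range(3)]
        ev = match_predictions([], gts)
        c = outcome_counts(ev, 0.5)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_two_predictions_one_gt_greedy(self):
        gt = block_mask((16, 16), 0, 8, 0, 8, ClassLabel.CM)
        good = block_mask((16, 16), 0, 8, 0, 8, ClassLabel.CM, score=0.9)
        worse = block_mask((16, 16), 0, 8, 2, 10, ClassLabel.CM, score=0.8)
        ev = match_predictions([good, worse], [gt])
        assert len(ev.matches) == 1
        assert ev.matches[0][0] == 0  # the higher-IoU prediction wins
        c = outcome_counts(ev, 0.5)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)

    def test_greedy_near_optimal_assignment_on_small_scenes(self):
        """Greedy IoU matching vs optimal (Hungarian) total-IoU assignment.

        Greedy provably equals the optimal assignment when IoU structure
        is unambiguous; divergences on ambiguous scenes are reported, and
        greedy never exceeds the optimum.
        """
        from scipy.optimize import linear_sum_assignment

        rng = np.random.default_rng(5)
        divergences = 0
        for trial in range(30):
            shape = (24, 24)
            preds, gts = [], []
            for _ in range(rng.integers(1, 5)):
                r, c = rng.integers(0, 14, 2)
                preds.append(block_mask(shape, r, r + 9, c, c + 9, ClassLabel.CM))
            for _ in range(rng.integers(1, 5)):
                r, c = rng.integers(0, 14, 2)
                gts.append(block_mask(shape, r, r + 9, c, c + 9, ClassLabel.CM))
            matches = greedy_match(preds, gts)
            greedy_total = sum(iou for _, _, iou in matches)
            from capquant.geometry import mask_iou

            cost = np.array([[mask_iou(p, g) for g in gts] for p in preds])
            ri, ci = linear_sum_assignment(-cost)
            best_total = cost[ri, ci].sum()
            assert greedy_total <= best_total + 1e-12
            if not np.isclose(greedy_total, best_total):
                divergences += 1
        assert divergences <= 6, f"greedy diverged in {divergences}/30 scenes"

    def test_empty_predictions_are_dropped_and_counted(self):
        gt = block_mask((8, 8), 0, 4, 0, 4, ClassLabel.CM)
        empty = InstanceMask(np.zeros((8, 8), bool), ClassLabel.CM)
        ev = match_predictions([empty], [gt])
        assert ev.n_dropped_empty == 1
        assert outcome_counts(ev, 0.5).fn == 1


class TestMetrics:
    @staticmethod
    def _perfect_pairs():
        gts = [
            block_mask((16, 16), 0, 6, 0, 6, ClassLabel.CM),
            block_mask((16, 16), 8, 14, 8, 14, ClassLabel.CAP),
        ]
        preds = [
            block_mask((16, 16), 0, 6, 0, 6, ClassLabel.CM, score=1.0),
            block_mask((16, 16), 8, 14, 8, 14, ClassLabel.CAP, score=1.0),
        ]
        return [(preds, gts)]

    def test_perfect_predictions_score_one_everywhere(self):
        report = evaluate_dataset(self._perfect_pairs())
        for setting in PRESETS:
            s = report.summary()[setting]
            assert s["mAP"] == s["mAR"] == s["F1"] == 1.0

    def test_no_predictions_zero_recall(self):
        gts = [block_mask((8, 8), 0, 4, 0, 4, ClassLabel.CM)]
        report = evaluate_dataset([([], gts)])
        s = report.summary()["iou_0.50"]
        assert s["mAR"] == 0.0 and s["F1"] == 0.0

    def test_sweep_has_exactly_ten_thresholds(self):
        assert len(SWEEP_50_95) == 10
        assert SWEEP_50_95[0] == 0.5 and SWEEP_50_95[-1] == 0.95

    def test_tp_monotone_non_increasing_in_phi(self):
        rng = np.random.default_rng(8)
        pairs = []
        for _ in range(5):
            shape = (24, 24)
            gts, preds = [], []
            for _ in range(4):
                r, c = rng.integers(0, 12, 2)
                gts.append(block_mask(shape, r, r + 10, c, c + 10, ClassLabel.CM))
                dr, dc = rng.integers(0, 4, 2)
                preds.append(
                    block_mask(
                        shape, r + dr, r + dr + 10, c + dc, c + dc + 10,
                        ClassLabel.CM, score=1.0,
                    )
                )
            pairs.append((preds, gts))
        evs = [match_predictions(p, g) for p, g in pairs]
        tps = []
        for phi in SWEEP_50_95:
            tps.append(sum(outcome_counts(ev, phi).tp for ev in evs))
        assert all(a >= b for a, b in zip(tps, tps[1:]))

    def test_no_ground_truth_is_error(self):
        with pytest.raises(ValueError):
            compute_metrics([], EvalConfig())

    def test_strict_coco_mode_turns_tn_into_fp_fn(self):
        a = block_mask((8, 8), 1, 5, 1, 5, ClassLabel.CM, score=1.0)
        b = block_mask((8, 8), 1, 5, 1, 5, ClassLabel.CAP)
        lax = match_predictions([a], [b], strict_coco=False)
        strict = match_predictions([a], [b], strict_coco=True)
        assert outcome_counts(lax, 0.5).tn == 1
        c = outcome_counts(strict, 0.5)
        assert (c.tn, c.fp, c.fn) == (0, 1, 1)


class TestScalars:
    def test_accuracy_caveat_scenario(self):
        # nine capillaries right, the single cardiomyocyte missed: 90%
        assert simple_accuracy(9, 10) == pytest.approx(0.90)

    @pytest.mark.parametrize("k", [1, 5])
    def test_accuracy_bounds(self, k):
        assert simple_accuracy(0, k) == 0.0
        assert simple_accuracy(k, k) == 1.0

    def test_accuracy_zero_total_rejected(self):
        with pytest.raises(ValueError):
            simple_accuracy(0, 0)

    def test_relative_error(self):
        assert relative_error(10, 10) == 0.0
        assert relative_error(12, 10) == pytest.approx(0.2)
        with pytest.raises(ZeroDivisionError):
            relative_error(1, 0)

    def test_aggregate_runs(self):
        mean, sd = aggregate_runs([1.0, 1.0, 1.0])
        assert (mean, sd) == (1.0, 0.0)
        mean, sd = aggregate_runs([0.0, 1.0])
        assert mean == 0.5 and sd == pytest.approx(np.sqrt(0.5))
        with pytest.raises(ValueError):
            aggregate_runs([0.3])
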