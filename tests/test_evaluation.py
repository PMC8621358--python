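"""Matching, AP interpolation and mask metrics against exhaustive oracles."""

import numpy as np
import pytest

from spikeseg.evaluation import (
    COCO_IOU_THRESHOLDS,
    MatchResult,
    ap_11point,
    ap_coco,
    box_iou,
    confusion_counts,
    detection_scores,
    evaluate_by_category,
    mask_metrics,
    match_detections,
    mean_ap,
    pr_curve,
)
from spikeseg.io_formats import BinaryMask, BoxAnnotation


def B(x0, y0, x1, y1, conf=None, category=None):
    return BoxAnnotation(x0, y0, x1, y1, confidence=conf, category=category)


# ---------------------------------------------------------------------------
# independent oracles


def iou_pixel_oracle(a: BoxAnnotation, b: BoxAnnotation) -> float:
    """Brute-force pixel-set IoU for integer boxes."""
    sa = {(x, y) for x in range(int(a.xmin), int(a.xmax)) for y in range(int(a.ymin), int(a.ymax))}
    sb = {(x, y) for x in range(int(b.xmin), int(b.xmax)) for y in range(int(b.ymin), int(b.ymax))}
    return len(sa & sb) / len(sa | sb)


def greedy_match_reference(preds, gts, threshold):
    """Plainly-written greedy matcher used only as a reference."""
    order = sorted(range(len(preds)),
                   key=lambda i: (-preds[i].confidence,
                                  -max((box_iou(preds[i], g) for g in gts), default=0.0), i))
    taken = set()
    tp_flags = {}
    for i in order:
        candidates = [(box_iou(preds[i], g), j) for j, g in enumerate(gts) if j not in taken]
        candidates = [(v, j) for v, j in candidates if v >= threshold]
        if candidates:
            v, j = max(candidates, key=lambda t: (t[0], -t[1]))
            taken.add(j)
            tp_flags[i] = True
        else:
            tp_flags[i] = False
    return order, tp_flags


def ap_bruteforce(preds_per_image, gts_per_image, threshold, recall_points):
    """Enumerate every confidence cutoff, rebuild the PR staircase from
    scratch, then integrate by the max-precision-at-recall>=r definition."""
    n_gt = sum(len(g) for g in gts_per_image)
    all_confs = sorted({p.confidence for preds in preds_per_image for p in preds}, reverse=True)
    points = []
    for cutoff in all_confs:
        tp = kept = 0
        for preds, gts in zip(preds_per_image, gts_per_image):
            sub = [p for p in preds if p.confidence >= cutoff]
            _, flags = greedy_match_reference(sub, gts, threshold)
            tp += sum(flags.values())
            kept += len(sub)
        points.append((tp / n_gt, tp / kept))
    ap = 0.0
    for r in recall_points:
        feasible = [p for rec, p in points if rec >= r - 1e-12]
        ap += max(feasible) if feasible else 0.0
    return ap / len(recall_points)


def random_instance(rng, max_preds=6, max_gts=4):
    def rand_box(conf=None):
        x0, y0 = rng.integers(0, 40, 2)
        w, h = rng.integers(1, 20, 2)
        return B(float(x0), float(y0), float(x0 + w), float(y0 + h), conf=conf)
    n_gt = int(rng.integers(1, max_gts + 1))
    n_pred = int(rng.integers(0, max_preds + 1))
    gts = [rand_box() for _ in range(n_gt)]
    confs = rng.permutation(np.linspace(0.05, 0.95, n_pred)) if n_pred else []
    preds = []
    for k in range(n_pred):
        if rng.random() < 0.6:  # perturb a ground truth
            g = gts[rng.integers(n_gt)]
            dx, dy = rng.integers(-5, 6, 2)
            x0, y0 = max(0.0, g.xmin + dx), max(0.0, g.ymin + dy)
            preds.append(B(x0, y0, max(x0 + 1, g.xmax + dx), max(y0 + 1, g.ymax + dy),
                           conf=round(float(confs[k]), 6)))
        else:
            preds.append(rand_box(conf=round(float(confs[k]), 6)))
    return preds, gts


# ---------------------------------------------------------------------------


class TestBoxIoU:
    def test_identical_boxes(self):
        assert box_iou(B(2, 3, 10, 12), B(2, 3, 10, 12)) == 1.0

    def test_disjoint_boxes(self):
        assert box_iou(B(0, 0, 5, 5), B(10, 10, 20, 20)) == 0.0

    def test_half_overlap_case(self):
        assert box_iou(B(0, 0, 10, 10), B(5, 0, 15, 10)) == pytest.approx(50 / 150, abs=1e-12)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            BoxAnnotation(0, 0, 0, 5)

    def test_matches_pixel_enumeration_oracle(self, rng):
        for _ in range(50):
            x0, y0 = rng.integers(0, 20, 2)
            w, h = rng.integers(1, 15, 2)
            a = B(int(x0), int(y0), int(x0 + w), int(y0 + h))
            x0, y0 = rng.integers(0, 20, 2)
            w, h = rng.integers(1, 15, 2)
            b = B(int(x0), int(y0), int(x0 + w), int(y0 + h))
            assert box_iou(a, b) == pytest.approx(iou_pixel_oracle(a, b), abs=1e-12)


class TestMatching:
    def test_perfect_single_detection(self):
        m = match_detections([B(0, 0, 10, 10, conf=0.9)], [B(0, 0, 10, 10)], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_two_predictions_one_gt_is_one_to_one(self):
        gt = B(0, 0, 10, 10)
        first = B(0, 2, 10, 12, conf=0.9)    # IoU 0.667
        second = B(0, 25, 10, 40, conf=0.8)
        m = match_detections([first, second], [gt], 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)
        assert m.matches[0][0] == 0

    def test_no_predictions(self):
        m = match_detections([], [B(0, 0, 5, 5)] * 3, 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 0, 3)

    def test_image_level_true_negative(self):
        assert match_detections([], [], 0.5).tn == 1
        assert match_detections([B(0, 0, 5, 5, conf=0.5)], [], 0.5).tn == 0

    def test_prediction_without_confidence_rejected(self):
        with pytest.raises(ValueError, match="confidence"):
            match_detections([B(0, 0, 5, 5)], [], 0.5)

    def test_no_gt_matched_twice_on_random_instances(self, rng):
        for _ in range(30):
            preds, gts = random_instance(rng)
            m = match_detections(preds, gts, 0.5)
            matched = [j for _, j, _ in m.matches]
            assert len(matched) == len(set(matched))
            assert m.tp + m.fn == len(gts)
            assert m.tp + m.fp == len(preds)


class TestDetectionScores:
    def test_printed_count_arithmetic(self):
        # 125 spikes in the test set, 119 detected, 3 false positives
        m = MatchResult([], tp=119, fp=3, fn=6)
        p, r, _, f1 = detection_scores(m)
        assert p == pytest.approx(119 / 122, abs=1e-12)
        assert r == pytest.approx(0.952, abs=1e-12)
        assert f1 == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_degenerate_ratios_are_nan_not_zero(self):
        with pytest.warns(UserWarning, match="undefined"):
            p, r, a, f1 = detection_scores(MatchResult([], tp=0, fp=0, fn=5))
        assert np.isnan(p) and r == 0.0 and np.isnan(f1)

    def test_accuracy_with_image_level_tn(self):
        _, _, a, _ = detection_scores(MatchResult([], tp=10, fp=0, fn=0, tn=2))
        assert a == 1.0


class TestAveragePrecision:
    def test_perfect_detector(self):
        preds = [[B(0, 0, 10, 10, conf=0.9)]]
        gts = [[B(0, 0, 10, 10)]]
        assert ap_11point(preds, gts, 0.5) == 1.0

    def test_only_false_positives(self):
        preds = [[B(50, 50, 60, 60, conf=0.9)]]
        gts = [[B(0, 0, 10, 10)]]
        assert ap_11point(preds, gts, 0.5) == 0.0

    def test_worked_two_prediction_example(self):
        """TP at conf 0.9 then FP at conf 0.8 over 2 GTs: AP = 6/11."""
        gts = [[B(0, 0, 10, 10), B(30, 30, 40, 40)]]
        preds = [[B(0, 0, 10, 10, conf=0.9), B(60, 60, 70, 70, conf=0.8)]]
        assert ap_11point(preds, gts, 0.5) == pytest.approx(6 / 11, abs=1e-12)

    def test_coco_threshold_grid(self):
        assert len(COCO_IOU_THRESHOLDS) == 10
        assert COCO_IOU_THRESHOLDS[0] == 0.5 and COCO_IOU_THRESHOLDS[-1] == 0.95

    def test_coco_sweep_with_iou_point_six_boxes(self):
        # every prediction has IoU exactly 0.6 with its ground truth:
        # thresholds 0.50, 0.55, 0.60 pass -> mean AP = 3/10
        gts, preds = [], []
        for k in range(3):
            g = B(0, k * 30.0, 10.0, k * 30.0 + 10.0)
            p = B(0, k * 30.0 + 2.5, 10.0, k * 30.0 + 12.5, conf=0.5 + 0.1 * k)
            gts.append(g)
            preds.append(p)
        per_threshold, mean = ap_coco([preds], [gts])
        assert per_threshold[0.5] == 1.0 and per_threshold[0.6] == 1.0
        assert per_threshold[0.65] == 0.0
        assert mean == pytest.approx(0.3, abs=1e-12)

    def test_perfect_detector_coco_mean_one(self):
        gts = [[B(0, 0, 10, 10), B(30, 30, 45, 50)]]
        preds = [[B(0, 0, 10, 10, conf=0.9), B(30, 30, 45, 50, conf=0.8)]]
        _, mean = ap_coco(preds, gts)
        assert mean == 1.0

    def test_zero_ground_truth_is_an_error(self):
        with pytest.raises(ValueError):
            ap_11point([[B(0, 0, 5, 5, conf=0.5)]], [[]], 0.5)

    def test_matches_bruteforce_oracle_on_200_seeded_instances(self):
        rng = np.random.default_rng(77)
        recall_11 = np.linspace(0, 1, 11)
        recall_101 = np.linspace(0, 1, 101)
        for _ in range(200):
            preds, gts = random_instance(rng)
            if not preds:
                continue
            mine = ap_11point([preds], [gts], 0.5)
            ref = ap_bruteforce([preds], [gts], 0.5, recall_11)
            assert abs(mine - ref) < 1e-10
            per_threshold, mean = ap_coco([preds], [gts])
            ref_mean = np.mean([ap_bruteforce([preds], [gts], t, recall_101)
                                for t in COCO_IOU_THRESHOLDS])
            assert abs(mean - ref_mean) < 1e-10

    def test_ap_invariant_to_monotone_confidence_transform(self, rng):
        for _ in range(20):
            preds, gts = random_instance(rng)
            if not preds:
                continue
            base = ap_11point([preds], [gts], 0.5)
            squashed = [B(p.xmin, p.ymin, p.xmax, p.ymax, conf=p.confidence ** 3) for p in preds]
            assert ap_11point([squashed], [gts], 0.5) == pytest.approx(base, abs=1e-12)

    def test_trailing_zero_iou_fp_never_increases_ap(self, rng):
        for _ in range(20):
            preds, gts = random_instance(rng)
            if not preds:
                continue
            base = ap_11point([preds], [gts], 0.5)
            min_conf = min(p.confidence for p in preds)
            junk = B(500, 500, 510, 510, conf=min_conf / 2)
            assert ap_11point([preds + [junk]], [gts], 0.5) <= base + 1e-12

    def test_recall_non_decreasing_along_curve(self, rng):
        for _ in range(10):
            preds, gts = random_instance(rng)
            if not preds:
                continue
            curve = pr_curve([preds], [gts], 0.5)
            assert (np.diff(curve.recall) >= -1e-15).all()
            assert ((curve.precision >= 0) & (curve.precision <= 1)).all()


class TestMeanAp:
    def test_single_and_pairwise(self):
        assert mean_ap([0.8]) == 0.8
        assert mean_ap([0.6, 1.0]) == pytest.approx(0.8)
        assert mean_ap([0.37] * 5) == pytest.approx(0.37)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_ap([])


class TestMaskMetrics:
    @staticmethod
    def _mask(coords, shape=(30, 30)):
        arr = np.zeros(shape, np.uint8)
        for r0, r1, c0, c1 in coords:
            arr[r0:r1, c0:c1] = 1
        return BinaryMask(arr)

    def test_identical_masks_all_ones(self):
        m = self._mask([(5, 15, 5, 15)])
        scores = mask_metrics(m, m)
        assert all(v == 1.0 for v in scores.values())

    def test_disjoint_equal_area(self):
        pred = self._mask([(0, 10, 0, 10)])
        gt = self._mask([(15, 25, 15, 25)])
        scores = mask_metrics(pred, gt)
        assert scores["dice"] == 0.0 and scores["jaccard"] == 0.0

    def test_half_overlap_counts(self):
        pred = self._mask([(0, 10, 0, 10)])      # 100 px
        gt = self._mask([(5, 15, 0, 10)])        # 100 px, 50 shared
        scores = mask_metrics(pred, gt)
        assert scores["dice"] == pytest.approx(0.5, abs=1e-12)
        assert scores["jaccard"] == pytest.approx(50 / 150, abs=1e-12)

    def test_dice_jaccard_identity_and_ordering(self, rng):
        for _ in range(20):
            pred = BinaryMask((rng.random((16, 16)) < 0.4).astype(np.uint8))
            gt = BinaryMask((rng.random((16, 16)) < 0.4).astype(np.uint8))
            s = mask_metrics(pred, gt)
            assert s["dice"] >= s["jaccard"]
            j = s["jaccard"]
            assert s["dice"] == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_empty_vs_empty_scores_one(self):
        empty = self._mask([])
        scores = mask_metrics(empty, empty)
        assert scores["dice"] == 1.0 and scores["aDC"] == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_metrics(self._mask([], (10, 10)), self._mask([], (12, 12)))


class TestCategoryEvaluation:
    def test_perfect_detector_single_category(self):
        gts = [[B(0, 0, 10, 10, category="top")]]
        preds = [[B(0, 0, 10, 10, conf=0.95)]]
        report = evaluate_by_category(preds, gts)
        assert report.per_category["top"].recall == 1.0
        assert report.per_category["top"].ap_11point == 1.0
        assert set(report.per_category) == {"top"}

    def test_missed_category_attribution(self):
        gts = [[B(0, 0, 10, 10, category="top"), B(30, 0, 40, 10, category="top"),
                B(60, 0, 70, 10, category="occluded_emergent")]]
        preds = [[B(0, 0, 10, 10, conf=0.9), B(30, 0, 40, 10, conf=0.8)]]
        report = evaluate_by_category(preds, gts)
        assert report.per_category["top"].recall == 1.0
        assert report.per_category["occluded_emergent"].recall == 0.0

    def test_mean_tp_confidence_reported(self):
        gts = [[B(0, 0, 10, 10, category="top"), B(30, 0, 40, 10, category="top")]]
        preds = [[B(0, 0, 10, 10, conf=0.9), B(30, 0, 40, 10, conf=0.7)]]
        report = evaluate_by_category(preds, gts)
        assert report.per_category["top"].mean_tp_confidence == pytest.approx(0.8)

    def test_untagged_gt_rejected(self):
        with pytest.raises(ValueError, match="category"):
            evaluate_by_category([[B(0, 0, 10, 10, conf=0.9)]], [[B(0, 0, 10, 10)]])

    def test_counts_match_generator_manifest(self):
        from spikeseg import synthetic_data as sd
        truth = sd.generate_scene(sd.SceneConfig(n_spikes=5, seed=21))
        preds = [B(b.xmin, b.ymin, b.xmax, b.ymax, conf=0.9) for b in truth.boxes]
        report = evaluate_by_category([preds], [truth.boxes])
        for cat, sub in report.per_category.items():
            assert sub.n_gt == sum(1 for b in truth.boxes if b.category == cat)
            assert sub.recall == 1.0


def test_confusion_counts_layout():
    table = confusion_counts(MatchResult([], tp=3, fp=1, fn=2, tn=1))
    assert table.loc["actual_spike", "predicted_spike"] == 3
    assert table.loc["actual_background", "predicted_background"] == 1


# ---------------------------------------------------------------------------
# property-based checks

from hypothesis import given, settings
from hypothesis import strategies as st

_coords = st.tuples(st.integers(0, 50), st.integers(0, 50), st.integers(1, 30), st.integers(1, 30))


@settings(derandomize=True, max_examples=200, deadline=None)
@given(_coords, _coords)
def test_box_iou_is_symmetric_bounded_and_identity_on_equal_boxes(c1, c2):
    a = B(c1[0], c1[1], c1[0] + c1[2], c1[1] + c1[3])
    b = B(c2[0], c2[1], c2[0] + c2[2], c2[1] + c2[3])
    iou = box_iou(a, b)
    assert iou == box_iou(b, a)
    assert 0.0 <= iou <= 1.0
    assert box_iou(a, a) == 1.0
    if c1 == c2:
        assert iou == 1.0


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.integers(0, 2**32 - 1), st.floats(0.05, 0.95))
def test_dice_jaccard_identity_on_random_masks(seed, density):
    rng = np.random.default_rng(seed)
    pred = BinaryMask((rng.random((10, 10)) < density).astype(np.uint8))
    gt = BinaryMask((rng.random((10, 10)) < density).astype(np.uint8))
    s = mask_metrics(pred, gt)
    j = s["jaccard"]
    assert s["dice"] == pytest.approx(2 * j / (1 + j), abs=1e-12)
    assert s["dice"] >= j
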