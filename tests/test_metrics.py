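"""Metric definitions against brute-force pixel-set oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from nnetseg.metrics import (
    ConfusionCounts,
    binary_miou,
    confusion_counts,
    dice,
    f1,
    image_metrics,
    miou,
    pr_curve,
    precision,
    read_report,
    recall,
    report_from_masks,
    write_report,
)

mask8 = arrays(np.uint8, (8, 8), elements=st.integers(0, 1))


def pixel_set_metrics(pred, gt):
    """Independent oracle: explicit coordinate-set operations."""
    p = {tuple(ix) for ix in np.argwhere(np.asarray(pred) == 1)}
    g = {tuple(ix) for ix in np.argwhere(np.asarray(gt) == 1)}
    tp, fp, fn = len(p & g), len(p - g), len(g - p)
    total = np.asarray(pred).size
    d = 2 * tp / (fp + 2 * tp + fn) if (tp or fp or fn) else 1.0
    prec = tp / (tp + fp) if (p or g) and (tp + fp) else (1.0 if not (p or g) else 0.0)
    rec = tp / (tp + fn) if (p or g) and (tp + fn) else (1.0 if not (p or g) else 0.0)
    iou_fg = tp / (fp + tp + fn) if (tp or fp or fn) else 1.0
    bg_inter = total - len(p | g)
    bg_union = total - tp
    iou_bg = bg_inter / bg_union if bg_union else 1.0
    return d, (iou_fg + iou_bg) / 2, prec, rec


class TestConfusionCounts:
    def test_identical_masks(self):
        gt = np.zeros((4, 4), np.uint8)
        gt[1:3, 1:3] = 1
        c = confusion_counts(gt, gt)
        assert (c.tp, c.fp, c.fn) == (4, 0, 0)

    def test_two_by_two_enumeration(self):
        c = confusion_counts(np.array([[1, 1], [0, 0]]), np.array([[1, 0], [1, 0]]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_empty_prediction(self):
        gt = np.zeros((3, 3), np.uint8)
        gt[0] = 1
        c = confusion_counts(np.zeros((3, 3), np.uint8), gt)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_counts_sum_to_pixel_total(self, rng):
        c = confusion_counts(rng.integers(0, 2, (8, 8)), rng.integers(0, 2, (8, 8)))
        assert c.total == 64

    def test_rejects_non_binary_and_mismatched(self):
        with pytest.raises(ValueError, match="0/1"):
            confusion_counts(np.array([[2]]), np.array([[1]]))
        with pytest.raises(ValueError, match="shape mismatch"):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPointMetrics:
    def test_worked_example(self):
        c = ConfusionCounts(tp=3, fp=1, fn=1, tn=11)
        assert dice(c) == precision(c) == recall(c) == f1(c) == 0.75

    def test_perfect_and_disjoint(self):
        perfect = ConfusionCounts(5, 0, 0, 4)
        disjoint = ConfusionCounts(0, 3, 3, 3)
        assert dice(perfect) == f1(perfect) == 1.0
        assert dice(disjoint) == precision(disjoint) == 0.0

    def test_both_empty_is_perfect_agreement(self):
        empty = ConfusionCounts(0, 0, 0, 9)
        assert dice(empty) == precision(empty) == recall(empty) == f1(empty) == 1.0

    def test_miou_arithmetic_mean_of_class_ious(self):
        fg = ConfusionCounts(6, 2, 2, 0)   # IoU 0.6
        bg = ConfusionCounts(8, 1, 1, 0)   # IoU 0.8
        assert miou([fg, bg]) == pytest.approx(0.7)

    def test_miou_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            miou([])


@settings(deadline=None, max_examples=150, derandomize=True)
@given(pred=mask8, gt=mask8)
def test_metrics_match_pixel_set_oracle(pred, gt):
    m = image_metrics(pred, gt)
    d, mi, p, r = pixel_set_metrics(pred, gt)
    assert m["dice"] == pytest.approx(d)
    assert m["miou"] == pytest.approx(mi)
    assert m["precision"] == pytest.approx(p)
    assert m["recall"] == pytest.approx(r)
    # Dice == F1 is an algebraic identity per image
    assert m["dice"] == pytest.approx(m["f1"])
    # Dice never falls below foreground IoU
    c = confusion_counts(pred, gt)
    fg_iou = c.tp / (c.fp + c.tp + c.fn) if (c.tp + c.fp + c.fn) else 1.0
    assert m["dice"] >= fg_iou - 1e-12


@settings(deadline=None, max_examples=60, derandomize=True)
@given(pred=mask8, gt=mask8, k=st.integers(0, 3))
def test_metrics_invariant_to_shared_rotation_and_flip(pred, gt, k):
    base = image_metrics(pred, gt)
    rot = image_metrics(np.rot90(pred, k), np.rot90(gt, k))
    flip = image_metrics(np.fliplr(pred), np.fliplr(gt))
    for m in base:
        assert base[m] == pytest.approx(rot[m])
        assert base[m] == pytest.approx(flip[m])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(pred=mask8, gt=mask8)
def test_miou_symmetric_in_arguments(pred, gt):
    assert binary_miou(pred, gt) == pytest.approx(binary_miou(gt, pred))


class TestPRCurve:
    def test_threshold_zero_gives_full_recall(self, rng):
        gt = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        gt[0, 0] = 1
        points = pr_curve([rng.random((6, 6))], [gt], thresholds=[0.0])
        assert points[0][0] == 1.0

    def test_above_one_threshold_empty_prediction_convention(self, rng):
        gt = np.ones((4, 4), np.uint8)
        (rec, prec), = pr_curve([rng.random((4, 4))], [gt], thresholds=[1.0 + 1e-9])
        # numpy clips nothing: p >= 1+eps is empty -> recall 0, precision 1.0
        assert rec == 0.0 and prec == 1.0

    def test_single_example_matches_hand_binarization(self):
        prob = np.array([[0.9, 0.4], [0.6, 0.1]])
        gt = np.array([[1, 0], [0, 1]], np.uint8)
        (rec, prec), = pr_curve([prob], [gt], thresholds=[0.5])
        assert rec == pytest.approx(0.5)    # TP=1 of 2 foreground
        assert prec == pytest.approx(0.5)   # TP=1 of 2 predicted

    def test_recall_non_increasing_in_threshold(self, rng):
        probs = [rng.random((8, 8)) for _ in range(3)]
        gts = [(rng.random((8, 8)) > 0.6).astype(np.uint8) for _ in range(3)]
        points = pr_curve(probs, gts)
        recalls = [r for r, _ in points]
        assert all(a >= b - 1e-12 for a, b in zip(recalls, recalls[1:]))

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError, match="differ in length"):
            pr_curve([np.zeros((2, 2))], [])


class TestReportRoundTrip:
    def test_write_then_read_preserves_summary(self, tmp_path, rng):
        preds = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(4)]
        gts = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(4)]
        report = report_from_masks(preds, gts, fold=2)
        csv_path, json_path = write_report(report, tmp_path / "metrics.csv")
        assert json_path.exists()
        loaded = read_report(csv_path)
        assert loaded.n == report.n
        assert loaded.mean() == pytest.approx(report.mean())
        assert loaded.sd() == pytest.approx(report.sd())
        assert "fold" in loaded.per_image.columns

    def test_empty_report_flags_n_zero(self, tmp_path):
        report = report_from_masks([], [])
        _, json_path = write_report(report, tmp_path / "empty.csv")
        import json
        with open(json_path) as fh:
            assert json.load(fh)["n"] == 0
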