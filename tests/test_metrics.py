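import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cariesseg.core import SegmentationMask, ShapeMismatchError
from cariesseg.metrics import (
    ConfusionCounts,
    confusion_counts,
    dice_score,
    evaluate_dataset,
    evaluate_pair,
    iou_score,
    mean_pixel_accuracy,
    pixel_accuracy_per_class,
)


def set_oracle(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Brute-force oracle using explicit pixel sets."""
    X = {(r, c) for r, c in zip(*np.nonzero(pred))}
    Y = {(r, c) for r, c in zip(*np.nonzero(truth))}
    all_px = {(r, c) for r in range(pred.shape[0]) for c in range(pred.shape[1])}
    iou = 1.0 if not (X | Y) else len(X & Y) / len(X | Y)
    dice = 1.0 if not X and not Y else 2 * len(X & Y) / (len(X) + len(Y))
    accs = []
    if Y:
        accs.append(len(X & Y) / len(Y))
    bg_truth = all_px - Y
    if bg_truth:
        accs.append(len(bg_truth - X) / len(bg_truth))
    return {"iou": iou, "dice": dice, "mpa": sum(accs) / len(accs)}


def _mask(arr):
    return SegmentationMask(np.asarray(arr, np.uint8))


def _worked_example():
    """4x4 fixture: truth 4 fg; pred hits 3, misses 1, adds 1 false fg."""
    truth = np.zeros((4, 4), np.uint8)
    truth[0, 0] = truth[0, 1] = truth[1, 0] = truth[1, 1] = 1
    pred = truth.copy()
    pred[1, 1] = 0  # miss
    pred[3, 3] = 1  # false positive
    return _mask(pred), _mask(truth)


class TestConfusionCounts:
    def test_perfect_prediction(self):
        m = np.zeros((4, 4), np.uint8)
        m[:2, :2] = 1
        c = confusion_counts(_mask(m), _mask(m))
        assert (c.tp, c.fp, c.fn, c.tn) == (4, 0, 0, 12)

    def test_all_background_prediction(self):
        truth = np.zeros((4, 4), np.uint8)
        truth[:2, :2] = 1
        c = confusion_counts(_mask(np.zeros((4, 4))), _mask(truth))
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 4, 12)

    def test_worked_example_counts(self):
        pred, truth = _worked_example()
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 11)
        assert c.total == 16

    def test_shape_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            confusion_counts(_mask(np.zeros((3, 3))), _mask(np.zeros((4, 4))))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestScores:
    def test_worked_example_values_exact(self):
        pred, truth = _worked_example()
        c = confusion_counts(pred, truth)
        assert iou_score(c) == 0.6
        assert dice_score(c) == 0.75
        assert mean_pixel_accuracy(c) == (3 / 4 + 11 / 12) / 2

    def test_identical_and_disjoint_masks(self):
        assert iou_score(ConfusionCounts(5, 0, 0, 10)) == 1.0
        assert dice_score(ConfusionCounts(5, 0, 0, 10)) == 1.0
        assert iou_score(ConfusionCounts(0, 3, 3, 10)) == 0.0
        assert dice_score(ConfusionCounts(0, 3, 3, 10)) == 0.0

    def test_both_empty_convention(self):
        c = ConfusionCounts(0, 0, 0, 16)
        assert iou_score(c) == 1.0
        assert dice_score(c) == 1.0
        assert mean_pixel_accuracy(c) == 1.0  # fg class excluded

    def test_mpa_degenerate_all_background(self):
        mpa, per_class = pixel_accuracy_per_class([12, 0], [12, 0])
        assert mpa == 1.0
        assert per_class == [1.0, None]

    def test_mpa_all_classes_absent_rejected(self):
        with pytest.raises(ValueError):
            pixel_accuracy_per_class([0, 0], [0, 0])

    def test_oracle_equivalence_on_random_masks(self, rng):
        """iou/dice/mPA match the pixel-set oracle to 1e-12 on 500 pairs."""
        for _ in range(500):
            h, w = rng.integers(1, 17, size=2)
            pred = (rng.random((h, w)) < rng.random()).astype(np.uint8)
            truth = (rng.random((h, w)) < rng.random()).astype(np.uint8)
            expected = set_oracle(pred, truth)
            c = confusion_counts(_mask(pred), _mask(truth))
            assert abs(iou_score(c) - expected["iou"]) <= 1e-12
            assert abs(dice_score(c) - expected["dice"]) <= 1e-12
            assert abs(mean_pixel_accuracy(c) - expected["mpa"]) <= 1e-12
            # Dice = 2 IoU / (1 + IoU)
            assert abs(dice_score(c) - 2 * iou_score(c) / (1 + iou_score(c))) <= 1e-12

    @given(
        tp=st.integers(0, 100), fp=st.integers(0, 100),
        fn=st.integers(0, 100), tn=st.integers(0, 100),
    )
    @settings(deadline=None, derandomize=True)
    def test_scores_bounded_and_symmetric(self, tp, fp, fn, tn):
        c = ConfusionCounts(tp, fp, fn, tn)
        swapped = ConfusionCounts(tp, fn, fp, tn)  # pred and truth exchanged
        assert 0.0 <= iou_score(c) <= 1.0
        assert 0.0 <= dice_score(c) <= 1.0
        assert iou_score(c) == iou_score(swapped)
        assert dice_score(c) == dice_score(swapped)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           fn=st.integers(1, 50), tn=st.integers(1, 50))
    @settings(deadline=None, derandomize=True)
    def test_correcting_a_missed_pixel_never_hurts(self, tp, fp, fn, tn):
        before = ConfusionCounts(tp, fp, fn, tn)
        after = ConfusionCounts(tp + 1, fp, fn - 1, tn)
        assert iou_score(after) >= iou_score(before)
        assert dice_score(after) >= dice_score(before)


class TestEvaluateDataset:
    def test_single_pair_micro_equals_per_image(self):
        pred, truth = _worked_example()
        micro = evaluate_dataset([pred], [truth], mode="micro")
        per = evaluate_dataset([pred], [truth], mode="per_image")
        for attr in ("mpa", "miou", "fg_iou", "dice"):
            assert getattr(micro, attr) == getattr(per, attr)

    def test_per_image_average_of_perfect_and_disjoint(self):
        a = np.zeros((4, 4), np.uint8)
        a[:2, :2] = 1
        b_truth = np.zeros((4, 4), np.uint8)
        b_truth[:2, :2] = 1
        b_pred = np.zeros((4, 4), np.uint8)
        b_pred[2:, 2:] = 1
        report = evaluate_dataset([_mask(a), _mask(b_pred)],
                                  [_mask(a), _mask(b_truth)], mode="per_image")
        assert report.fg_iou == 0.5  # mean of 1.0 and 0.0

    def test_micro_dice_iou_identity(self, rng):
        preds, truths = [], []
        for _ in range(6):
            preds.append(_mask((rng.random((9, 9)) < 0.3).astype(np.uint8)))
            truths.append(_mask((rng.random((9, 9)) < 0.3).astype(np.uint8)))
        report = evaluate_dataset(preds, truths, mode="micro")
        assert abs(report.dice - 2 * report.fg_iou / (1 + report.fg_iou)) <= 1e-12

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([], [], mode="micro")

    def test_miou_is_two_class_mean(self):
        pred, truth = _worked_example()
        row = evaluate_pair(pred, truth)
        assert row["miou"] == (row["fg_iou"] + row["bg_iou"]) / 2
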