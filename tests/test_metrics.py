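"""Evaluation metrics against independent pixel-enumeration oracles."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellcryst.annotio import AnnotatedImage, Instance
from cellcryst.metrics import (
    BoxScoreSummary,
    ObjectCountPair,
    PixelConfusion,
    delta_object,
    delta_object_normalized,
    evaluate_dataset,
    f_measure,
    jaccard,
    mean_box_score,
    pixel_confusion,
    precision,
    recall,
)
from cellcryst.segmodel import InstancePrediction


def _masks_from_pixels(pixels, shape=(2, 2)):
    m = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return [m]


def test_pixel_confusion_enumerated_example():
    pred = _masks_from_pixels([(0, 0), (0, 1), (1, 0)])
    gt = _masks_from_pixels([(0, 1), (1, 0), (1, 1)])
    c = pixel_confusion(pred, gt, (2, 2))
    assert (c.tp, c.fp, c.fn) == (2, 1, 1)


def test_worked_formula_example():
    c = PixelConfusion(tp=2, fp=1, fn=1)
    assert precision(c) == pytest.approx(2 / 3)
    assert recall(c) == pytest.approx(2 / 3)
    assert f_measure(c) == pytest.approx(2 / 3)
    assert jaccard(c) == pytest.approx(0.5)


def test_empty_side_conventions():
    both_empty = PixelConfusion(0, 0, 0)
    assert (precision(both_empty), recall(both_empty),
            f_measure(both_empty), jaccard(both_empty)) == (1, 1, 1, 1)
    only_gt = PixelConfusion(0, 0, 5)
    assert (precision(only_gt), recall(only_gt),
            f_measure(only_gt), jaccard(only_gt)) == (0, 0, 0, 0)
    only_pred = PixelConfusion(0, 5, 0)
    assert (precision(only_pred), recall(only_pred),
            f_measure(only_pred), jaccard(only_pred)) == (0, 0, 0, 0)


def test_pixel_metrics_match_enumeration_oracle_exactly():
    """200 random 16x16 mask pairs, exact rational comparison."""
    rng = np.random.default_rng(2024)
    for _ in range(200):
        pred = rng.random((16, 16)) < rng.uniform(0.05, 0.6)
        gt = rng.random((16, 16)) < rng.uniform(0.05, 0.6)
        c = pixel_confusion([pred], [gt], (16, 16))
        # oracle: enumerate every pixel independently
        tp = sum(bool(pred[r, c_]) and bool(gt[r, c_])
                 for r in range(16) for c_ in range(16))
        fp = sum(bool(pred[r, c_]) and not gt[r, c_]
                 for r in range(16) for c_ in range(16))
        fn = sum(not pred[r, c_] and bool(gt[r, c_])
                 for r in range(16) for c_ in range(16))
        assert (c.tp, c.fp, c.fn) == (tp, fp, fn)
        # bitwise equality with the correctly-rounded exact rational
        if tp + fp:
            assert precision(c) == float(Fraction(tp, tp + fp))
        if tp + fn:
            assert recall(c) == float(Fraction(tp, tp + fn))
        if tp + fp + fn:
            assert f_measure(c) == float(Fraction(2 * tp, 2 * tp + fp + fn))
            assert jaccard(c) == float(Fraction(tp, tp + fp + fn))


@given(tp=st.integers(0, 1000), fp=st.integers(0, 1000), fn=st.integers(0, 1000))
@settings(max_examples=1000, derandomize=True)
def test_jaccard_equals_f_over_two_minus_f(tp, fp, fn):
    if tp + fp + fn == 0:
        return
    c = PixelConfusion(tp, fp, fn)
    f = f_measure(c)
    assert jaccard(c) == pytest.approx(f / (2 - f), rel=1e-12, abs=1e-15)


def test_delta_object_examples():
    pairs = [ObjectCountPair(4, 3), ObjectCountPair(2, 2)]
    assert delta_object(pairs) == pytest.approx(0.5)
    assert delta_object_normalized(pairs) == pytest.approx(0.125)
    # one miss plus one spurious detection on the same image cancel out
    assert delta_object([ObjectCountPair(2, 2)]) == 0.0
    assert delta_object([ObjectCountPair(g, g) for g in range(1, 5)]) == 0.0


def test_delta_object_symmetric_in_over_and_under_segmentation():
    for g, k in [(5, 2), (3, 3), (10, 1)]:
        over = delta_object([ObjectCountPair(g, g + k)])
        under = delta_object([ObjectCountPair(g, g - k)])
        assert over == under == k


def test_delta_on_caps_at_one_and_handles_empty_images():
    assert delta_object_normalized([ObjectCountPair(2, 7)]) == 1.0  # raw 2.5
    assert delta_object_normalized([ObjectCountPair(0, 0)]) == 0.0
    assert delta_object_normalized([ObjectCountPair(0, 3)]) == 1.0
    with pytest.raises(ValueError):
        delta_object([])
    with pytest.raises(ValueError):
        delta_object_normalized([])


def _annotated_with_masks(masks, labels=None, shape=(16, 16)):
    labels = labels or ["crystal_G"] * len(masks)
    return AnnotatedImage(shape=shape, instances=[
        Instance(label=lb, mask=m) for lb, m in zip(labels, masks)])


def _prediction(mask, score=0.9, label="crystal_G"):
    return InstancePrediction(mask=mask, score=score, label=label)


def test_evaluate_dataset_perfect_predictions():
    rng = np.random.default_rng(5)
    gts, preds = [], []
    for _ in range(5):
        mask = np.zeros((16, 16), dtype=bool)
        r, c = rng.integers(2, 10, 2)
        mask[r:r + 4, c:c + 4] = True
        gts.append(_annotated_with_masks([mask]))
        preds.append([_prediction(mask.copy(), score=1.0)])
    report = evaluate_dataset(preds, gts, score_threshold=0.7)
    assert report.mean_f == 1.0
    assert report.mean_j == 1.0
    assert report.mean_delta_o == 0.0
    assert report.mean_delta_on == 0.0
    assert report.to_row() == {"F(%)": 100.0, "J(%)": 100.0, "dO": 0.0, "dON(%)": 0.0}


def test_mean_jaccard_never_exceeds_mean_f():
    rng = np.random.default_rng(11)
    gts, preds = [], []
    for _ in range(20):
        gt = rng.random((16, 16)) < 0.3
        pr = rng.random((16, 16)) < 0.3
        gts.append(_annotated_with_masks([gt]))
        preds.append([_prediction(pr)] if pr.any() else [])
    report = evaluate_dataset(preds, gts)
    assert report.mean_j <= report.mean_f + 1e-12


def test_raising_threshold_never_increases_prediction_count():
    rng = np.random.default_rng(13)
    masks = [rng.random((16, 16)) < 0.2 for _ in range(6)]
    preds = [[_prediction(m, score=s) for m, s in
              zip(masks, [0.5, 0.6, 0.7, 0.8, 0.9, 1.0])]]
    gts = [_annotated_with_masks([masks[0]])]
    counts = []
    for thr in [0.0, 0.3, 0.55, 0.75, 0.95, 1.0]:
        report = evaluate_dataset(preds, gts, score_threshold=thr)
        counts.append(report.per_image[0].pred_count)
    assert counts == sorted(counts, reverse=True)


def test_pixel_metrics_invariant_under_instance_splitting_but_counts_not():
    """F/J see only mask unions; object counts see each instance."""
    mask = np.zeros((16, 16), dtype=bool)
    mask[4:12, 4:12] = True
    left, right = mask.copy(), mask.copy()
    left[:, 8:] = False
    right[:, :8] = False
    pred = [_prediction(mask.copy())]
    whole = evaluate_dataset([pred], [_annotated_with_masks([mask])])
    split = evaluate_dataset([pred], [_annotated_with_masks([left, right])])
    relabeled = evaluate_dataset([pred], [_annotated_with_masks(
        [mask], labels=["crystal_H"])], gt_labels={"crystal_H"})
    assert whole.mean_f == split.mean_f == relabeled.mean_f
    assert whole.mean_j == split.mean_j == relabeled.mean_j
    assert whole.mean_delta_o == 0.0
    assert split.mean_delta_o == 1.0  # 2 gt instances vs 1 prediction
    assert split.mean_delta_on == 0.5


def test_evaluate_dataset_rejects_misaligned_lists():
    gt = _annotated_with_masks([np.ones((4, 4), dtype=bool)], shape=(4, 4))
    with pytest.raises(ValueError, match="prediction lists"):
        evaluate_dataset([[], []], [gt])


def test_mean_box_score_all_filter():
    m = np.zeros((8, 8), dtype=bool)
    m[2:4, 2:4] = True
    preds = [_prediction(m, score=0.8), _prediction(m, score=1.0)]
    summary = mean_box_score(preds, "all")
    assert summary == BoxScoreSummary(mean_score=pytest.approx(0.9), n=2)


def test_mean_box_score_partitions_by_cell_occupancy():
    # cell 0 holds two predictions (coexisting), cell 1 holds one (isolated),
    # one prediction lies outside every cell and joins neither group
    shape = (24, 24)
    cell0 = np.zeros(shape, dtype=bool)
    cell0[0:10, 0:10] = True
    cell1 = np.zeros(shape, dtype=bool)
    cell1[14:22, 14:22] = True

    def blob(r, c):
        m = np.zeros(shape, dtype=bool)
        m[r:r + 2, c:c + 2] = True
        return m

    preds = [
        _prediction(blob(1, 1), score=0.8),
        _prediction(blob(6, 6), score=0.6),
        _prediction(blob(16, 16), score=0.9),
        _prediction(blob(11, 11), score=0.99),  # between the cells
    ]
    iso = mean_box_score(preds, "isolated_in_cell", cell_masks=[cell0, cell1])
    coex = mean_box_score(preds, "coexisting_in_cell", cell_masks=[cell0, cell1])
    assert iso == BoxScoreSummary(mean_score=pytest.approx(0.9), n=1)
    assert coex.n == 2
    assert coex.mean_score == pytest.approx(0.7)
    assert iso.n + coex.n == 3  # the outside prediction is in neither group
    with pytest.raises(ValueError, match="cell masks"):
        mean_box_score(preds, "isolated_in_cell")
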