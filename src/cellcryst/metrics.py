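"""Segmentation evaluation metrics for crystal screening.

Pixel-wise indicators compare the union of predicted foreground against the
union of ground-truth foreground, per image:

    P = tp / (tp + fp)          precision
    R = tp / (tp + fn)          recall
    F = 2 P R / (P + R)         F-measure (harmonic mean)
    J = tp / (tp + fp + fn)     Jaccard index (intersection over union)

Object-wise indicators compare instance counts per image i with ground-truth
count N_i and predicted count M_i:

    dO  = (1/n) sum_i |N_i - M_i|                 (delta object)
    dON = (1/n) sum_i min(1, |N_i - M_i| / N_i)   (normalized delta object)

dON is bounded in [0, 1] and robust to differences in object density between
images; lower is better.  An image with N_i = 0 contributes 0 when M_i = 0
and 1 otherwise.

Empty-image conventions for the pixel metrics: if prediction and ground truth
are both empty, P = R = F = J = 1 (a correct negative); if exactly one side
is empty, all four are 0.

Dataset-level values are macro averages: each indicator is computed per image
and then arithmetically averaged over the n images.  Micro-averaged pixel
metrics (pooled counts) are also reported but are not the default summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geometry import mask_centroid
from .annotio import AnnotatedImage, Instance

__all__ = [
    "PixelConfusion",
    "ObjectCountPair",
    "PerImageMetrics",
    "MetricReport",
    "BoxScoreSummary",
    "pixel_confusion",
    "precision",
    "recall",
    "f_measure",
    "jaccard",
    "delta_object",
    "delta_object_normalized",
    "evaluate_dataset",
    "mean_box_score",
    "DEFAULT_SCORE_THRESHOLD",
]

DEFAULT_SCORE_THRESHOLD = 0.7


@dataclass(frozen=True)
class PixelConfusion:
    """Per-image true/false positive and false negative pixel counts."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class ObjectCountPair:
    """Ground-truth and predicted object counts for one image."""

    gt_count: int
    pred_count: int

    def __post_init__(self):
        if self.gt_count < 0 or self.pred_count < 0:
            raise ValueError("object counts must be non-negative")


@dataclass(frozen=True)
class PerImageMetrics:
    precision: float
    recall: float
    f_measure: float
    jaccard: float
    delta_object: float
    delta_object_normalized: float
    gt_count: int
    pred_count: int


@dataclass
class MetricReport:
    """Dataset-level evaluation summary (one table row) plus per-image detail."""

    per_image: list[PerImageMetrics]
    mean_f: float
    mean_j: float
    mean_delta_o: float
    mean_delta_on: float
    micro_f: float
    micro_j: float
    n: int
    score_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.per_image])

    def to_row(self) -> dict[str, float]:
        """Percentages to two decimals, matching the reporting convention."""
        return {
            "F(%)": round(100 * self.mean_f, 2),
            "J(%)": round(100 * self.mean_j, 2),
            "dO": round(self.mean_delta_o, 2),
            "dON(%)": round(100 * self.mean_delta_on, 2),
        }


def _union(masks: list[np.ndarray], image_shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(image_shape, dtype=bool)
    for m in masks:
        if m.shape != tuple(image_shape):
            raise ValueError(
                f"mask shape {m.shape} does not match image shape {tuple(image_shape)}"
            )
        out |= m
    return out


def pixel_confusion(pred_masks: list[np.ndarray], gt_masks: list[np.ndarray],
                    image_shape: tuple[int, int]) -> PixelConfusion:
    """Pixel confusion between the unions of predicted and ground-truth masks.

    Overlapping instances (e.g. crystal clusters) are unioned before counting,
    so the pixel metrics see a single foreground set per side.
    """
    pred = _union(pred_masks, image_shape)
    gt = _union(gt_masks, image_shape)
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    return PixelConfusion(tp=tp, fp=fp, fn=fn)


def precision(c: PixelConfusion) -> float:
    if c.tp + c.fp == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / (c.tp + c.fp)


def recall(c: PixelConfusion) -> float:
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def f_measure(c: PixelConfusion) -> float:
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    # 2PR/(P+R) == 2tp/(2tp + fp + fn); the latter is stable when P = R = 0
    return 2 * c.tp / (2 * c.tp + c.fp + c.fn)


def jaccard(c: PixelConfusion) -> float:
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fp + c.fn)


def delta_object(pairs: list[ObjectCountPair]) -> float:
    """Mean absolute object-count difference over images.

    Because the difference is taken per image, a miss and a spurious detection
    on the same image cancel out; the indicator is blind to such compensating
    errors by construction.
    """
    if not pairs:
        raise ValueError("delta_object requires at least one image")
    return float(np.mean([abs(p.gt_count - p.pred_count) for p in pairs]))


def _delta_on_term(p: ObjectCountPair) -> float:
    if p.gt_count == 0:
        return 0.0 if p.pred_count == 0 else 1.0
    return min(1.0, abs(p.gt_count - p.pred_count) / p.gt_count)


def delta_object_normalized(pairs: list[ObjectCountPair]) -> float:
    """Mean per-image object-count error normalized by ground-truth count.

    Each image's term is |N_i - M_i| / N_i capped at 1, so the average lies in
    [0, 1] and images with very different object densities weigh equally.
    """
    if not pairs:
        raise ValueError("delta_object_normalized requires at least one image")
    return float(np.mean([_delta_on_term(p) for p in pairs]))


def evaluate_dataset(
    predictions: list[list["InstancePrediction | Instance"]],
    ground_truth: list[AnnotatedImage],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    gt_labels: set[str] | None = None,
) -> MetricReport:
    """Evaluate per-image predictions against ground truth and average.

    Parameters
    ----------
    predictions
        One list of predicted instances per image, aligned with
        ``ground_truth``.  Instances whose score is below ``score_threshold``
        are discarded (instances without a score always pass).
    ground_truth
        Annotated images; ``gt_labels`` restricts which ground-truth classes
        count as foreground (default: all crystal classes present).
    """
    if len(predictions) != len(ground_truth):
        raise ValueError(
            f"got {len(predictions)} prediction lists for {len(ground_truth)} images"
        )
    if not 0.0 <= score_threshold <= 1.0:
        raise ValueError("score_threshold must lie in [0, 1]")
    per_image = []
    pooled_tp = pooled_fp = pooled_fn = 0
    for preds, gt in zip(predictions, ground_truth):
        kept = [p for p in preds
                if getattr(p, "score", None) is None or p.score >= score_threshold]
        labels = gt_labels
        if labels is None:
            labels = {lb for lb in gt.labels() if lb.startswith("crystal")}
        gt_masks = gt.masks(labels=labels)
        pred_masks = [_pred_mask(p, gt.shape) for p in kept]
        conf = pixel_confusion(pred_masks, gt_masks, gt.shape)
        pair = ObjectCountPair(gt_count=len(gt_masks), pred_count=len(kept))
        per_image.append(PerImageMetrics(
            precision=precision(conf),
            recall=recall(conf),
            f_measure=f_measure(conf),
            jaccard=jaccard(conf),
            delta_object=float(abs(pair.gt_count - pair.pred_count)),
            delta_object_normalized=_delta_on_term(pair),
            gt_count=pair.gt_count,
            pred_count=pair.pred_count,
        ))
        pooled_tp += conf.tp
        pooled_fp += conf.fp
        pooled_fn += conf.fn
    pooled = PixelConfusion(tp=pooled_tp, fp=pooled_fp, fn=pooled_fn)
    return MetricReport(
        per_image=per_image,
        mean_f=float(np.mean([m.f_measure for m in per_image])),
        mean_j=float(np.mean([m.jaccard for m in per_image])),
        mean_delta_o=float(np.mean([m.delta_object for m in per_image])),
        mean_delta_on=float(np.mean([m.delta_object_normalized for m in per_image])),
        micro_f=f_measure(pooled),
        micro_j=jaccard(pooled),
        n=len(per_image),
        score_threshold=score_threshold,
    )


def _pred_mask(p, shape):
    if hasattr(p, "get_mask"):
        return p.get_mask(shape)
    return p.mask


@dataclass(frozen=True)
class BoxScoreSummary:
    mean_score: float
    n: int


def mean_box_score(
    predictions: list["InstancePrediction"],
    context_filter: str = "all",
    cell_masks: list[np.ndarray] | None = None,
) -> BoxScoreSummary:
    """Mean objectness score of predictions, optionally split by cell context.

    ``context_filter``:

    - ``all``: every prediction.
    - ``isolated_in_cell``: predictions whose mask centroid lies inside a cell
      containing exactly one accepted prediction.
    - ``coexisting_in_cell``: predictions inside a cell containing more than
      one accepted prediction.

    Each prediction is assigned to at most one cell (the first whose mask
    contains its centroid), so the isolated/coexisting groups partition the
    in-cell predictions.  Predictions outside every cell are excluded from the
    per-cell contexts.  Returns mean NaN when the group is empty.
    """
    if context_filter not in ("all", "isolated_in_cell", "coexisting_in_cell"):
        raise ValueError(f"unknown context filter: {context_filter!r}")
    scored = [p for p in predictions if p.score is not None]
    if context_filter == "all":
        scores = [p.score for p in scored]
    else:
        if cell_masks is None:
            raise ValueError("per-cell context filters require cell masks")
        assignment: dict[int, list] = {}
        for p in scored:
            cx, cy = mask_centroid(p.mask)
            r, c = int(cy), int(cx)
            for cell_idx, cm in enumerate(cell_masks):
                if 0 <= r < cm.shape[0] and 0 <= c < cm.shape[1] and cm[r, c]:
                    assignment.setdefault(cell_idx, []).append(p)
                    break
        scores = []
        for members in assignment.values():
            if context_filter == "isolated_in_cell" and len(members) == 1:
                scores.extend(p.score for p in members)
            elif context_filter == "coexisting_in_cell" and len(members) > 1:
                scores.extend(p.score for p in members)
    if not scores:
        return BoxScoreSummary(mean_score=float("nan"), n=0)
    return BoxScoreSummary(mean_score=float(np.mean(scores)), n=len(scores))
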