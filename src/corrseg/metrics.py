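"""Corrective-annotation metrics, area errors and the training stopping rule.

During interactive training the user's green/red corrections double as an
implicit ground truth: the corrected segmentation is *assumed accurate*, so
precision, recall, dice and accuracy can be computed per training image
without a separate manually annotated validation set.  A trailing rolling
mean of one metric (by default dice over a 10-image window reaching 0.95)
gives an objective criterion for when to stop training.

Conventions on degenerate counts: when an image has neither predicted nor
reference foreground all metrics are 1 — a model that correctly predicts
"nothing here" should not be penalized, which matters for sparse subjects.
Signed area error is predicted minus corrected area, so positive means
over-prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .masks import (
    AnnotationMask,
    BinaryMask,
    ConfusionCounts,
    _require_same_shape,
    apply_correction,
)

METRIC_NAMES = ("precision", "recall", "dice", "accuracy")

#: CSV column contract for training-log export.
LOG_COLUMNS = [
    "image_id",
    "index",
    "precision",
    "recall",
    "dice",
    "accuracy",
    "predicted_area_px",
    "corrected_area_px",
    "area_error_px",
]


# ---------------------------------------------------------------------------
# Scalar metrics
# ---------------------------------------------------------------------------

def precision(cc: ConfusionCounts) -> float:
    """TP / (TP + FP); with no positive predictions, 1 if nothing was
    missed (fn == 0) else 0."""
    pos = cc.tp + cc.fp
    if pos == 0:
        return 1.0 if cc.fn == 0 else 0.0
    return cc.tp / pos


def recall(cc: ConfusionCounts) -> float:
    """TP / (TP + FN); with no reference foreground, 1 if nothing was
    falsely predicted (fp == 0) else 0."""
    actual = cc.tp + cc.fn
    if actual == 0:
        return 1.0 if cc.fp == 0 else 0.0
    return cc.tp / actual


def dice(cc: ConfusionCounts) -> float:
    """Overlap score 2TP / (2TP + FP + FN), the harmonic mean of precision
    and recall; 1 when both masks are empty."""
    denom = 2 * cc.tp + cc.fp + cc.fn
    if denom == 0:
        return 1.0
    return 2 * cc.tp / denom


def accuracy(cc: ConfusionCounts) -> float:
    """(TP + TN) / all pixels."""
    if cc.total == 0:
        raise ValueError("accuracy undefined for zero total pixel count")
    return (cc.tp + cc.tn) / cc.total


# ---------------------------------------------------------------------------
# Corrective (annotation-implied) confusion
# ---------------------------------------------------------------------------

def corrective_confusion(pred: BinaryMask, ann: AnnotationMask) -> ConfusionCounts:
    """Confusion of a prediction against its own corrected segmentation.

    Equivalent to ``confusion(pred, apply_correction(pred, ann))`` but
    computed directly: fp = green strokes inside the prediction,
    fn = red strokes outside it.
    """
    _require_same_shape(pred, ann)
    fp = int(np.count_nonzero(ann.green & pred.data))
    fn = int(np.count_nonzero(ann.red & ~pred.data))
    tp = pred.foreground_area() - fp
    tn = pred.data.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def area_error(pred: BinaryMask, ann: AnnotationMask) -> int:
    """Signed area error in pixels: predicted minus corrected area.

    Equals (green strokes inside the prediction) − (red strokes outside
    it); positive means the model over-predicts.
    """
    _require_same_shape(pred, ann)
    removed = int(np.count_nonzero(ann.green & pred.data))
    added = int(np.count_nonzero(ann.red & ~pred.data))
    return removed - added


# ---------------------------------------------------------------------------
# Training logs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricRecord:
    """Per-image metrics in training order.

    ``annotated_fraction`` records how much of the image the user actually
    stroked; incomplete corrections bias every metric optimistically, so
    the fraction is carried for diagnostics rather than corrected for.
    """

    image_id: str
    index: int
    precision: float
    recall: float
    dice: float
    accuracy: float
    predicted_area: int
    corrected_area: int
    area_error: int
    annotated_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.area_error != self.predicted_area - self.corrected_area:
            raise ValueError("area_error must equal predicted_area - corrected_area")


class TrainingLog:
    """Ordered sequence of :class:`MetricRecord`, indices 0..n-1."""

    def __init__(self, records: Sequence[MetricRecord]) -> None:
        records = list(records)
        for i, rec in enumerate(records):
            if rec.index != i:
                raise ValueError(
                    f"record {rec.image_id!r} has index {rec.index}, expected {i}"
                )
        self.records = records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def series(self, metric: str) -> np.ndarray:
        if metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_NAMES}")
        return np.array([getattr(r, metric) for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "image_id": r.image_id,
                "index": r.index,
                "precision": r.precision,
                "recall": r.recall,
                "dice": r.dice,
                "accuracy": r.accuracy,
                "predicted_area_px": r.predicted_area,
                "corrected_area_px": r.corrected_area,
                "area_error_px": r.area_error,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=LOG_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def evaluate_pair(
    pred: BinaryMask, ann: AnnotationMask, image_id: str = "", index: int = 0
) -> MetricRecord:
    """Score one (prediction, correction) pair."""
    cc = corrective_confusion(pred, ann)
    predicted = pred.foreground_area()
    err = area_error(pred, ann)
    return MetricRecord(
        image_id=image_id,
        index=index,
        precision=precision(cc),
        recall=recall(cc),
        dice=dice(cc),
        accuracy=accuracy(cc),
        predicted_area=predicted,
        corrected_area=predicted - err,
        area_error=err,
        annotated_fraction=ann.annotated_fraction(),
    )


def evaluate_sequence(
    pairs: Iterable[tuple[BinaryMask, AnnotationMask]],
    image_ids: Optional[Sequence[str]] = None,
) -> TrainingLog:
    """Score an ordered sequence of (prediction, correction) pairs.

    Per-pair failures are re-raised with the offending image id attached.
    """
    records = []
    for i, (pred, ann) in enumerate(pairs):
        image_id = image_ids[i] if image_ids is not None else f"image_{i:04d}"
        try:
            records.append(evaluate_pair(pred, ann, image_id=image_id, index=i))
        except ValueError as exc:
            raise ValueError(f"{image_id}: {exc}") from exc
    return TrainingLog(records)


# ---------------------------------------------------------------------------
# Rolling statistics and the stopping rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StoppingRule:
    """Stop training when the trailing mean of ``metric`` over ``window_n``
    consecutive images reaches ``threshold``."""

    metric: str = "dice"
    window_n: int = 10
    threshold: float = 0.95

    def __post_init__(self) -> None:
        if self.metric not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.window_n < 1:
            raise ValueError("window_n must be >= 1")
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")


def rolling_mean(
    log: TrainingLog, metric: str = "dice", window_n: int = 10
) -> list[tuple[int, float]]:
    """Trailing unweighted mean of a metric.

    Returns ``(index, mean)`` pairs where the value at index ``i`` averages
    records ``i-window_n+1 .. i``; indices before the window fills are absent.
    """
    if window_n < 1:
        raise ValueError("window_n must be >= 1")
    values = log.series(metric)
    if len(values) < window_n:
        return []
    csum = np.concatenate([[0.0], np.cumsum(values)])
    means = (csum[window_n:] - csum[:-window_n]) / window_n
    return [(i + window_n - 1, float(m)) for i, m in enumerate(means)]


def stopping_index(log: TrainingLog, rule: StoppingRule = StoppingRule()) -> Optional[int]:
    """Smallest record index at which the rolling mean exceeds the rule's
    threshold, or ``None`` if it never does (or the log is shorter than the
    window).

    The comparison is strict: a window sitting exactly at the threshold
    (e.g. nine perfect images and one at half credit against a 0.95
    threshold) has not yet demonstrated sustained performance, so training
    continues one more image.
    """
    for idx, mean in rolling_mean(log, rule.metric, rule.window_n):
        if mean > rule.threshold:
            return idx
    return None
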