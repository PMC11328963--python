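"""Dataset-level model validation against manually annotated masks.

Pooled (micro-averaged) metrics are computed from confusion counts summed
over all images — equivalent to overlaying every annotation at once — never
from averaging per-image metric values, which would weight small and large
images equally.  Area agreement between predicted and corrected/true areas
is summarized with a Pearson correlation and an ordinary least-squares fit
of predicted on true, whose intercept reads as a systematic over- or
under-prediction.

Success classification uses the thresholds conventional in benthic
segmentation studies: precision >= 0.71, recall >= 0.75, dice >= 0.74,
accuracy >= 0.76 (all inclusive, all four required).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .masks import BinaryMask, ConfusionCounts, confusion
from .metrics import accuracy, dice, precision, recall
from .scaling import ScaleFactor, area_to_cm2

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SuccessThresholds:
    precision: float = 0.71
    recall: float = 0.75
    dice: float = 0.74
    accuracy: float = 0.76


@dataclass(frozen=True)
class SuccessResult:
    success: bool
    flags: dict  # metric name -> bool (threshold met)


def classify_success(
    precision_value: float,
    recall_value: float,
    dice_value: float,
    accuracy_value: float,
    thresholds: SuccessThresholds = SuccessThresholds(),
) -> SuccessResult:
    """A model is successful iff all four metrics meet their thresholds
    (inclusive)."""
    values = {
        "precision": precision_value,
        "recall": recall_value,
        "dice": dice_value,
        "accuracy": accuracy_value,
    }
    for name, v in values.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    flags = {name: v >= getattr(thresholds, name) for name, v in values.items()}
    return SuccessResult(success=all(flags.values()), flags=flags)


@dataclass(frozen=True)
class ValidationReport:
    """Pooled validation of one model over a set of images."""

    n_images: int
    counts: ConfusionCounts
    precision: float
    recall: float
    dice: float
    accuracy: float
    success: SuccessResult

    def summary(self) -> str:
        lines = [
            f"images: {self.n_images}",
            f"pooled counts: tp={self.counts.tp} fp={self.counts.fp} "
            f"fn={self.counts.fn} tn={self.counts.tn}",
            f"precision: {self.precision:.4f}",
            f"recall:    {self.recall:.4f}",
            f"dice:      {self.dice:.4f}",
            f"accuracy:  {self.accuracy:.4f}",
            f"success:   {self.success.success} {self.success.flags}",
        ]
        return "\n".join(lines)


def pooled_metrics(
    pairs: Iterable[tuple[BinaryMask, BinaryMask]],
    thresholds: SuccessThresholds = SuccessThresholds(),
) -> ValidationReport:
    """Micro-averaged metrics over (prediction, manual truth) pairs.

    Confusion counts are summed across images first; the metric formulas
    are applied once to the totals.
    """
    total = ConfusionCounts(0, 0, 0, 0)
    n = 0
    for pred, manual in pairs:
        total = total + confusion(pred, manual)
        n += 1
    if n == 0:
        raise ValueError("pooled_metrics needs at least one image pair")
    p, r, d, a = precision(total), recall(total), dice(total), accuracy(total)
    return ValidationReport(
        n_images=n,
        counts=total,
        precision=p,
        recall=r,
        dice=d,
        accuracy=a,
        success=classify_success(p, r, d, a, thresholds),
    )


@dataclass(frozen=True)
class AreaDifferenceSummary:
    """Per-image area agreement between two measurement methods, in cm²."""

    n_images: int
    mean_abs_cm2: float
    sd_abs_cm2: float
    mean_pct: float  # |difference| as % of the manual area
    sd_pct: float
    mean_signed_cm2: float  # predicted - manual; sign kept for transparency
    n_excluded_zero_manual: int = 0


def area_difference_summary(
    pairs: Sequence[tuple[BinaryMask, BinaryMask]],
    scale: ScaleFactor,
) -> AreaDifferenceSummary:
    """Mean absolute area difference (± sample sd) between predicted and
    manual masks, and the same as a percentage of the manual area.

    Images with zero manual area cannot contribute a percentage; they are
    dropped from the percentage summary with a logged count.
    """
    abs_diffs = []
    signed_diffs = []
    pcts = []
    n_zero = 0
    for pred, manual in pairs:
        a_pred = area_to_cm2(pred.foreground_area(), scale)
        a_man = area_to_cm2(manual.foreground_area(), scale)
        signed = a_pred - a_man
        signed_diffs.append(signed)
        abs_diffs.append(abs(signed))
        if a_man > 0:
            pcts.append(abs(signed) / a_man * 100.0)
        else:
            n_zero += 1
    if not abs_diffs:
        raise ValueError("area_difference_summary needs at least one image pair")
    if n_zero:
        logger.info("%d image(s) with zero manual area excluded from %% summary", n_zero)

    def _sd(values: list[float]) -> float:
        return float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")

    return AreaDifferenceSummary(
        n_images=len(abs_diffs),
        mean_abs_cm2=float(np.mean(abs_diffs)),
        sd_abs_cm2=_sd(abs_diffs),
        mean_pct=float(np.mean(pcts)) if pcts else float("nan"),
        sd_pct=_sd(pcts) if pcts else float("nan"),
        mean_signed_cm2=float(np.mean(signed_diffs)),
        n_excluded_zero_manual=n_zero,
    )


@dataclass(frozen=True)
class AgreementStats:
    """OLS fit of predicted areas on corrected/true areas."""

    n: int
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    mean_signed_error: float  # mean(y - x), cm²
    slope_stderr: float
    intercept_stderr: float


def area_agreement(x: Sequence[float], y: Sequence[float]) -> AgreementStats:
    """Agreement between reference areas ``x`` and predicted areas ``y``.

    Ordinary least squares of y on x; the intercept is interpretable as a
    systematic over-prediction when the slope is near 1.  The mean signed
    error is reported alongside because intercept and mean offset answer
    subtly different questions.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and congruent")
    if x.size < 3:
        raise ValueError("need at least 3 points for a regression")
    if np.var(x) == 0:
        raise ValueError("x has zero variance; regression is degenerate")
    fit = stats.linregress(x, y)
    return AgreementStats(
        n=int(x.size),
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        mean_signed_error=float(np.mean(y - x)),
        slope_stderr=float(fit.stderr),
        intercept_stderr=float(fit.intercept_stderr),
    )
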