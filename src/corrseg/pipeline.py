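"""Directory-level orchestration: pairing files, running the metric,
measurement, calibration and validation passes, and rule-based anomaly
flagging.

Files across ``predictions/``, ``annotations/``, ``truths/`` and
``lasers/`` directories are paired by basename (stem), processed in
lexicographic order; mismatched basenames are reported, never silently
skipped.  Anomaly flags are an automated, conservative stand-in for the
visual post-processing a human would do on segmentation thumbnails: they
mark frames for exclusion from summary statistics but rows are never
deleted from the output (audit trail).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .masks import (
    BinaryMask,
    read_annotation,
    read_mask,
    write_annotation,
    write_mask,
)
from .metrics import StoppingRule, TrainingLog, evaluate_sequence, rolling_mean, stopping_index
from .regions import measure_mask, regions_to_frame
from .scaling import (
    DEFAULT_LASER_SEPARATION_CM,
    DEFAULT_MIN_REGION_PX,
    DEFAULT_REFERENCE_CM,
    ScaleFactor,
    area_to_cm2,
    calibrate_from_lasers,
    fixed_reference_scale,
)
from .validate import pooled_metrics

logger = logging.getLogger(__name__)

_MASK_SUFFIXES = {".png", ".tif", ".tiff", ".bmp", ".gif", ".jpg", ".jpeg"}


class BasenameMismatchError(ValueError):
    """Directories that must pair by basename do not."""


@dataclass
class AnomalyRules:
    """Thresholds for rule-based frame flagging; advisory by default."""

    expected_region_count: Optional[int] = None
    area_jump_z: float = 4.0  # robust z-score on total area (median/MAD)


@dataclass(frozen=True)
class AnomalyFlag:
    image_id: str
    rule: str  # zero_regions | region_count_change | area_jump | laser_excluded
    detail: str


@dataclass
class RunConfig:
    """Configuration for the pipeline passes; defaults mirror each
    module's own defaults."""

    predictions_dir: Optional[str] = None
    annotations_dir: Optional[str] = None
    truths_dir: Optional[str] = None
    lasers_dir: Optional[str] = None
    output_dir: str = "corrseg_out"
    foreground_rule: Optional[str] = None  # None -> any non-zero channel
    colour_tolerance: int = 30
    connectivity: int = 8
    stopping: StoppingRule = field(default_factory=StoppingRule)
    scale_source: Optional[str] = None  # "lasers" | "fixed_reference" | None
    laser_separation_cm: float = DEFAULT_LASER_SEPARATION_CM
    min_laser_region_px: int = DEFAULT_MIN_REGION_PX
    reference_px: Optional[float] = None
    reference_cm: float = DEFAULT_REFERENCE_CM
    anomaly: AnomalyRules = field(default_factory=AnomalyRules)
    allow_partial: bool = False
    write_plots: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        stopping = StoppingRule(**raw.pop("stopping", {}))
        anomaly = AnomalyRules(**raw.pop("anomaly", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(stopping=stopping, anomaly=anomaly, **raw)


def _list_masks(directory) -> dict[str, Path]:
    d = Path(directory)
    if not d.is_dir():
        raise FileNotFoundError(f"not a directory: {d}")
    return {
        p.stem: p
        for p in sorted(d.iterdir())
        if p.suffix.lower() in _MASK_SUFFIXES
    }


def pair_basenames(
    dir_a, dir_b, allow_partial: bool = False
) -> list[tuple[str, Path, Path]]:
    """Pair files in two directories by basename, in lexicographic order.

    Unmatched basenames raise (listing every offender) unless
    ``allow_partial``, in which case they are logged and skipped.
    """
    a = _list_masks(dir_a)
    b = _list_masks(dir_b)
    only_a = sorted(set(a) - set(b))
    only_b = sorted(set(b) - set(a))
    if (only_a or only_b) and not allow_partial:
        raise BasenameMismatchError(
            f"unmatched basenames: {only_a} only in {dir_a}; {only_b} only in {dir_b}"
        )
    if only_a or only_b:
        logger.warning(
            "skipping unmatched basenames: %s / %s", only_a, only_b
        )
    common = sorted(set(a) & set(b))
    return [(name, a[name], b[name]) for name in common]


# ---------------------------------------------------------------------------
# Passes
# ---------------------------------------------------------------------------

def run_metrics(config: RunConfig) -> TrainingLog:
    """Score a training sequence from predictions/ + annotations/ and write
    the log CSV, the rolling-mean series and a stopping report."""
    if not config.predictions_dir or not config.annotations_dir:
        raise ValueError("run_metrics needs predictions_dir and annotations_dir")
    pairs = pair_basenames(
        config.predictions_dir, config.annotations_dir, config.allow_partial
    )
    preds_anns = []
    ids = []
    for name, pred_path, ann_path in pairs:
        preds_anns.append(
            (
                read_mask(pred_path, config.foreground_rule),
                read_annotation(ann_path, config.colour_tolerance),
            )
        )
        ids.append(name)
    log = evaluate_sequence(preds_anns, image_ids=ids)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.to_csv(out / "metrics.csv")
    rule = config.stopping
    roll = rolling_mean(log, rule.metric, rule.window_n)
    pd.DataFrame(roll, columns=["index", f"rolling_{rule.metric}"]).to_csv(
        out / "rolling.csv", index=False
    )
    stop = stopping_index(log, rule)
    (out / "stopping.txt").write_text(
        f"metric: {rule.metric}\nwindow_n: {rule.window_n}\n"
        f"threshold: {rule.threshold}\nstopping_index: {stop}\n"
        f"n_images: {len(log)}\n"
    )
    if config.write_plots and len(log):
        _plot_log(log, roll, rule, out / "metrics.png")
    return log


def _plot_log(log: TrainingLog, roll, rule: StoppingRule, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
    idx = np.arange(len(log))
    for name in ("precision", "recall", "dice", "accuracy"):
        ax1.plot(idx, log.series(name), label=name, lw=1)
    if roll:
        rx, ry = zip(*roll)
        ax1.plot(rx, ry, "k--", label=f"rolling {rule.metric} (n={rule.window_n})")
        ax1.axhline(rule.threshold, color="grey", ls=":", lw=1)
    ax1.set_ylabel("metric")
    ax1.legend(fontsize=8)
    ax2.plot(idx, [r.area_error for r in log], "o-", ms=2, lw=1)
    ax2.axhline(0, color="grey", lw=0.5)
    ax2.set_ylabel("area error (px)")
    ax2.set_xlabel("training image index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_calibrate(config: RunConfig) -> pd.DataFrame:
    """Per-frame laser calibration report from lasers/."""
    if not config.lasers_dir:
        raise ValueError("run_calibrate needs lasers_dir")
    rows = []
    for name, path in sorted(_list_masks(config.lasers_dir).items()):
        mask = read_mask(path, config.foreground_rule)
        det, scale = calibrate_from_lasers(
            mask,
            config.laser_separation_cm,
            config.min_laser_region_px,
            config.connectivity,
        )
        rows.append(
            dict(
                image_id=name,
                n_laser_regions=det.n_regions,
                pixel_distance=det.pixel_distance,
                px_per_cm=None if scale is None else scale.px_per_cm,
                status=det.status,
                reason=det.reason,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["image_id", "n_laser_regions", "pixel_distance", "px_per_cm", "status", "reason"],
    )
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "calibration.csv", index=False)
    return df


def run_measure(config: RunConfig) -> tuple[pd.DataFrame, list[AnomalyFlag]]:
    """Measure regions for every prediction mask; add cm² columns when a
    scale source is configured; flag anomalous frames."""
    if not config.predictions_dir:
        raise ValueError("run_measure needs predictions_dir")
    masks = {
        name: read_mask(path, config.foreground_rule)
        for name, path in sorted(_list_masks(config.predictions_dir).items())
    }
    if not masks:
        raise ValueError(f"no mask files in {config.predictions_dir}")
    tables = {
        name: measure_mask(mask, config.connectivity) for name, mask in masks.items()
    }
    df = regions_to_frame(tables)

    scales: dict[str, Optional[ScaleFactor]] = {}
    laser_flags: list[AnomalyFlag] = []
    if config.scale_source == "fixed_reference":
        if config.reference_px is None:
            raise ValueError("fixed_reference scaling needs reference_px")
        scale = fixed_reference_scale(config.reference_px, config.reference_cm)
        scales = {name: scale for name in masks}
    elif config.scale_source == "lasers":
        if not config.lasers_dir:
            raise ValueError("laser scaling needs lasers_dir")
        laser_paths = _list_masks(config.lasers_dir)
        for name in masks:
            if name not in laser_paths:
                scales[name] = None
                laser_flags.append(
                    AnomalyFlag(name, "laser_excluded", "no laser mask for frame")
                )
                continue
            det, scale = calibrate_from_lasers(
                read_mask(laser_paths[name], config.foreground_rule),
                config.laser_separation_cm,
                config.min_laser_region_px,
                config.connectivity,
            )
            scales[name] = scale
            if scale is None:
                laser_flags.append(
                    AnomalyFlag(name, "laser_excluded", det.reason or "excluded")
                )
    if config.scale_source:
        def to_cm2(row):
            scale = scales.get(row["image_id"])
            return np.nan if scale is None else area_to_cm2(row["area_px"], scale)

        df["area_cm2"] = df.apply(to_cm2, axis=1)
        df["scale_status"] = [
            "ok" if scales.get(i) is not None else "excluded" for i in df["image_id"]
        ]

    per_frame = df.groupby("image_id", sort=True).agg(
        n_regions=("label", lambda s: int((s > 0).sum())),
        total_area=("area_px", "sum"),
    ).reset_index()
    flags = laser_flags + flag_anomalies(per_frame, config.anomaly)
    flagged = {f.image_id for f in flags}
    df["flagged"] = df["image_id"].isin(flagged)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "regions.csv", index=False)
    pd.DataFrame(
        [dataclasses.asdict(f) for f in flags],
        columns=["image_id", "rule", "detail"],
    ).to_csv(out / "anomalies.csv", index=False)
    return df, flags


def flag_anomalies(
    table: pd.DataFrame, rules: Optional[AnomalyRules] = None
) -> list[AnomalyFlag]:
    """Rule-based anomaly flags over an ordered per-frame table.

    ``table`` needs columns ``image_id``, ``n_regions`` and ``total_area``
    (frame order = row order).  Each flagged frame carries exactly one
    primary rule; precedence is zero_regions > region_count_change >
    area_jump.
    """
    rules = rules or AnomalyRules()
    required = {"image_id", "n_regions", "total_area"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    flags: list[AnomalyFlag] = []
    counts = table["n_regions"].to_numpy()
    areas = table["total_area"].to_numpy(dtype=float)
    ids = table["image_id"].tolist()

    expected = rules.expected_region_count
    if expected is None:
        med_count = float(np.median(counts))
        expect_regions = med_count > 0
    else:
        expect_regions = expected > 0

    med = float(np.median(areas))
    mad = float(np.median(np.abs(areas - med)))
    scale = 1.4826 * mad

    for i, image_id in enumerate(ids):
        if counts[i] == 0 and expect_regions:
            flags.append(
                AnomalyFlag(image_id, "zero_regions", "no regions where regions expected")
            )
            continue
        if expected is not None and counts[i] != expected:
            flags.append(
                AnomalyFlag(
                    image_id,
                    "region_count_change",
                    f"{counts[i]} regions, expected {expected}",
                )
            )
            continue
        dev = abs(areas[i] - med)
        z = np.inf if scale == 0 and dev > 0 else (dev / scale if scale > 0 else 0.0)
        if z > rules.area_jump_z:
            flags.append(
                AnomalyFlag(
                    image_id,
                    "area_jump",
                    f"total area {areas[i]:.0f} vs median {med:.0f} (robust z={z:.1f})",
                )
            )
    return flags


def run_validate(config: RunConfig):
    """Pooled validation of predictions/ against truths/."""
    if not config.predictions_dir or not config.truths_dir:
        raise ValueError("run_validate needs predictions_dir and truths_dir")
    pairs = pair_basenames(config.predictions_dir, config.truths_dir, config.allow_partial)
    mask_pairs = [
        (read_mask(p, config.foreground_rule), read_mask(t, config.foreground_rule))
        for _, p, t in pairs
    ]
    report = pooled_metrics(mask_pairs)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "validation.txt").write_text(report.summary() + "\n")
    pd.DataFrame(
        [
            dict(
                n_images=report.n_images,
                tp=report.counts.tp,
                fp=report.counts.fp,
                fn=report.counts.fn,
                tn=report.counts.tn,
                precision=report.precision,
                recall=report.recall,
                dice=report.dice,
                accuracy=report.accuracy,
                success=report.success.success,
            )
        ]
    ).to_csv(out / "validation.csv", index=False)
    return report


def simulate_dataset(
    out_dir,
    tspec: Optional[synthetic.TrajectorySpec] = None,
    px_per_cm: float = 50.0,
    dot_radius: int = 3,
) -> pd.DataFrame:
    """Write a synthetic dataset tree: images/, truths/, predictions/,
    annotations/, lasers/ plus a manifest CSV of generator parameters and
    bookkeeping counts."""
    from PIL import Image

    tspec = tspec or synthetic.TrajectorySpec()
    out = Path(out_dir)
    for sub in ("images", "truths", "predictions", "annotations", "lasers"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    items = synthetic.generate_training_sequence(tspec)
    rng = np.random.default_rng(tspec.seed + 1)
    laser_seeds = rng.integers(0, 2**31 - 1, size=len(items))
    rows = []
    for i, item in enumerate(items):
        name = f"frame_{i:04d}"
        Image.fromarray(item.image).save(out / "images" / f"{name}.png")
        write_mask(item.truth, out / "truths" / f"{name}.png")
        write_mask(item.prediction, out / "predictions" / f"{name}.png")
        write_annotation(item.annotation, out / "annotations" / f"{name}.png")
        laser = synthetic.generate_laser_frame(
            px_per_cm,
            dot_radius=dot_radius,
            width=item.truth.width,
            height=item.truth.height,
            seed=int(laser_seeds[i]),
        )
        write_mask(laser, out / "lasers" / f"{name}.png")
        cc = item.true_confusion
        rows.append(
            dict(
                image_id=name,
                index=i,
                seed=tspec.seed,
                completeness=tspec.correction_completeness,
                decay_tau=tspec.decay_tau,
                px_per_cm=px_per_cm,
                tp=cc.tp,
                fp=cc.fp,
                fn=cc.fn,
                tn=cc.tn,
                truth_area_px=item.truth.foreground_area(),
                predicted_area_px=item.prediction.foreground_area(),
            )
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
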