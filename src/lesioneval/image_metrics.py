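"""Image-level diagnostic performance.

Confusion semantics, the five diagnostic metrics with exact binomial
confidence intervals, ROC over a fixed threshold grid with trapezoidal AUC
and Youden-optimal cutoffs, the IoU>=0.5 localization ratio, and the
mode-stratified report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .frame_dataset import FrameRecord, ImagingMode
from .geometry import best_match

__all__ = [
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticReport",
    "ROCPoint",
    "ROCCurve",
    "image_score",
    "classify_image",
    "confusion_at_threshold",
    "clopper_pearson",
    "diagnostic_metrics",
    "default_threshold_grid",
    "roc_curve",
    "youden_optimal",
    "format_threshold_range",
    "iou50_ratio",
    "stratified_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Image counts of the four confusion classes."""

    n_tp: int
    n_fn: int
    n_fp: int
    n_tn: int

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_fn", "n_fp", "n_tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.n_tp + self.n_fn

    @property
    def n_negative(self) -> int:
        return self.n_fp + self.n_tn

    @property
    def total(self) -> int:
        return self.n_positive + self.n_negative


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its two-sided exact binomial CI and raw counts."""

    value: float
    ci_low: float
    ci_high: float
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.value <= self.ci_high):
            raise ValueError("point estimate must lie inside its CI")


@dataclass(frozen=True)
class DiagnosticReport:
    """The five diagnostic metrics; a metric with a zero denominator is None."""

    sensitivity: Optional[MetricEstimate]
    specificity: Optional[MetricEstimate]
    ppv: Optional[MetricEstimate]
    npv: Optional[MetricEstimate]
    accuracy: MetricEstimate
    counts: ConfusionCounts


@dataclass(frozen=True)
class ROCPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ROCCurve:
    points: tuple
    auc: float
    optimal_thresholds: tuple = field(default=())

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc must lie in [0, 1], got {self.auc}")


def image_score(frame: FrameRecord) -> float:
    """Reduce a frame's predicted boxes to one decision score.

    The maximum box confidence; 0 when the frame carries no predictions.
    """
    if not frame.pred_boxes:
        return 0.0
    return max(score for _, score in frame.pred_boxes)


def classify_image(gt_present: bool, pred_present: bool) -> str:
    """One confusion label per image, regardless of box counts or overlap."""
    if gt_present:
        return "TP" if pred_present else "FN"
    return "FP" if pred_present else "TN"


def confusion_at_threshold(
    frames: Iterable[FrameRecord], threshold: float
) -> ConfusionCounts:
    """Count confusion classes with ``pred_present = image_score >= threshold``."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    tally = {"TP": 0, "FN": 0, "FP": 0, "TN": 0}
    for frame in frames:
        label = classify_image(frame.lesion_positive, image_score(frame) >= threshold)
        tally[label] += 1
    return ConfusionCounts(
        n_tp=tally["TP"], n_fn=tally["FN"], n_fp=tally["FP"], n_tn=tally["TN"]
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval via beta quantiles.

    The lower bound is exactly 0 for ``k = 0`` and the upper bound exactly 1
    for ``k = n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 <= k <= n):
        raise ValueError(f"k must lie in [0, n], got k={k}, n={n}")
    if not (0.0 < level < 1.0):
        raise ValueError(f"level must lie in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _estimate(k: int, n: int, level: float) -> Optional[MetricEstimate]:
    if n == 0:
        return None
    lower, upper = clopper_pearson(k, n, level)
    return MetricEstimate(
        value=k / n, ci_low=lower, ci_high=upper, numerator=k, denominator=n
    )


def diagnostic_metrics(counts: ConfusionCounts, level: float = 0.95) -> DiagnosticReport:
    """The five diagnostic metrics with per-metric exact binomial CIs.

    Each CI is Clopper-Pearson on that metric's own numerator/denominator
    pair. Metrics with a zero denominator are reported as ``None``, never
    coerced to 0 or 1.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    return DiagnosticReport(
        sensitivity=_estimate(counts.n_tp, counts.n_positive, level),
        specificity=_estimate(counts.n_tn, counts.n_negative, level),
        ppv=_estimate(counts.n_tp, counts.n_tp + counts.n_fp, level),
        npv=_estimate(counts.n_tn, counts.n_tn + counts.n_fn, level),
        accuracy=_estimate(counts.n_tp + counts.n_tn, counts.total, level),
        counts=counts,
    )


def default_threshold_grid() -> np.ndarray:
    """Thresholds 0.01, 0.02, ..., 0.99."""
    return np.round(np.arange(1, 100) / 100.0, 2)


def roc_curve(
    frames: Sequence[FrameRecord], grid: Optional[Sequence[float]] = None
) -> ROCCurve:
    """ROC over the threshold grid with trapezoidal AUC.

    Anchor points (0,0) and (1,1) in (1-specificity, sensitivity) space are
    appended before integration so perfect separation reaches AUC = 1.
    Optimal thresholds are every grid point attaining the maximum Youden J.
    """
    frames = list(frames)
    scores = np.array([image_score(f) for f in frames])
    positive = np.array([f.lesion_positive for f in frames], dtype=bool)
    n_pos = int(positive.sum())
    n_neg = len(frames) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("frames must contain at least one positive and one negative")
    thresholds = default_threshold_grid() if grid is None else np.asarray(grid, float)

    points = []
    for t in thresholds:
        flagged = scores >= t
        sens = float((flagged & positive).sum()) / n_pos
        spec = float((~flagged & ~positive).sum()) / n_neg
        points.append(ROCPoint(threshold=float(t), sensitivity=sens, specificity=spec))

    fpr = np.array([1.0 - p.specificity for p in points])
    tpr = np.array([p.sensitivity for p in points])
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((tpr, fpr))
    auc = float(np.trapezoid(tpr[order], fpr[order]))

    best_j = max(p.youden_j for p in points)
    optimal = tuple(
        p.threshold for p in points if math.isclose(p.youden_j, best_j, abs_tol=1e-12)
    )
    return ROCCurve(points=tuple(points), auc=auc, optimal_thresholds=optimal)


def youden_optimal(curve: ROCCurve) -> tuple:
    """All grid thresholds attaining the maximum Youden J."""
    if not curve.points:
        raise ValueError("empty ROC curve")
    return curve.optimal_thresholds


def format_threshold_range(thresholds: Sequence[float]) -> str:
    """Render a tied threshold set as ``0.27`` or ``0.05-0.06``."""
    if not thresholds:
        raise ValueError("empty threshold set")
    lo, hi = min(thresholds), max(thresholds)
    if lo == hi:
        return f"{lo:g}"
    return f"{lo:g}-{hi:g}"


@dataclass(frozen=True)
class IoURatio:
    numerator: int
    denominator: int

    @property
    def ratio(self) -> float:
        return self.numerator / self.denominator

    @property
    def percentage(self) -> float:
        return 100.0 * self.ratio


def iou50_ratio(
    tp_frames: Sequence[FrameRecord],
    threshold: float,
    iou_cut: float = 0.5,
    strict: bool = False,
) -> IoURatio:
    """Fraction of TP frames whose best-matched predicted box reaches the IoU cut.

    Only predicted boxes scoring at/above ``threshold`` enter the matching.
    ``strict=True`` requires IoU strictly above the cut instead of at/above.
    """
    if not tp_frames:
        raise ValueError("tp_frames must be non-empty")
    hits = 0
    for frame in tp_frames:
        if not frame.lesion_positive:
            raise ValueError(
                f"frame {frame.frame_index} of case {frame.case_id} is not "
                "lesion-positive; iou50_ratio expects TP frames"
            )
        preds = [b for b, s in frame.pred_boxes if s >= threshold]
        if not preds:
            raise ValueError(
                f"frame {frame.frame_index} of case {frame.case_id} has no "
                f"predicted box at threshold {threshold}; not a TP frame"
            )
        top = max(m.iou for m in best_match(frame.gt_boxes, preds))
        if (top > iou_cut) if strict else (top >= iou_cut):
            hits += 1
    return IoURatio(numerator=hits, denominator=len(tp_frames))


@dataclass(frozen=True)
class StratumRow:
    """One row of the stratified report."""

    stratum: str
    threshold_label: str
    threshold: float
    n_positive: int
    n_total: int
    youden_j: float
    report: DiagnosticReport
    iou_ratio: Optional[IoURatio]

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n_total


def _tp_frames_at(frames: Sequence[FrameRecord], threshold: float) -> list[FrameRecord]:
    return [
        f
        for f in frames
        if f.lesion_positive and image_score(f) >= threshold
    ]


def _row(
    frames: Sequence[FrameRecord],
    stratum: str,
    threshold: float,
    label: str,
    iou_cut: float,
) -> StratumRow:
    counts = confusion_at_threshold(frames, threshold)
    report = diagnostic_metrics(counts)
    sens = report.sensitivity.value if report.sensitivity else float("nan")
    spec = report.specificity.value if report.specificity else float("nan")
    tp = _tp_frames_at(frames, threshold)
    ratio = iou50_ratio(tp, threshold, iou_cut=iou_cut) if tp else None
    return StratumRow(
        stratum=stratum,
        threshold_label=label,
        threshold=threshold,
        n_positive=counts.n_positive,
        n_total=counts.total,
        youden_j=sens + spec - 1.0,
        report=report,
        iou_ratio=ratio,
    )


def stratified_report(
    frames: Sequence[FrameRecord],
    grid: Optional[Sequence[float]] = None,
    iou_cut: float = 0.5,
) -> list[StratumRow]:
    """Per-mode and overall report rows at Youden-optimal operating points.

    The overall row uses the overall optimal threshold. Each mode gets a row
    at its own optimal threshold plus, when different, one at the overall
    optimal threshold. Empty strata are skipped with a warning.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("frames must be non-empty")

    overall_curve = roc_curve(frames, grid)
    overall_opt = overall_curve.optimal_thresholds
    overall_t = overall_opt[0]
    rows = [
        _row(frames, "Overall", overall_t, format_threshold_range(overall_opt), iou_cut)
    ]

    for mode in (ImagingMode.WLI, ImagingMode.CE, ImagingMode.NBI):
        sub = [f for f in frames if f.mode is mode]
        if not sub:
            logger.warning("stratum %s has no frames; row omitted", mode.value)
            continue
        try:
            curve = roc_curve(sub, grid)
        except ValueError:
            logger.warning("stratum %s is single-class; row omitted", mode.value)
            continue
        opt = curve.optimal_thresholds
        rows.append(_row(sub, mode.value, opt[0], format_threshold_range(opt), iou_cut))
        if overall_t not in opt:
            rows.append(_row(sub, mode.value, overall_t, f"{overall_t:g}", iou_cut))
    return rows
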