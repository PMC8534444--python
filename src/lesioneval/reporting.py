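"""Composed pipelines, run configuration, and report rendering.

Stages communicate only through documented file formats (annotation JSON,
stream CSVs, report CSV/JSON), so each stage is independently testable and
no stage mutates its inputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .frame_dataset import apply_exclusions, read_annotations
from .image_metrics import (
    MetricEstimate,
    StratumRow,
    default_threshold_grid,
    roc_curve,
    stratified_report,
)
from .lesion_latency import (
    LatencySummary,
    LesionEvent,
    detection_latency,
    summarize_latencies,
)
from .temporal_filter import DetectionStream, persistence_filter

__all__ = [
    "RunConfig",
    "ConfigError",
    "SUMMARY_SCHEMA_VERSION",
    "report_rows_to_frame",
    "roc_points_to_frame",
    "run_image_pipeline",
    "read_stream_csv",
    "write_stream_csv",
    "run_latency_pipeline",
]

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = "1.0"


class ConfigError(ValueError):
    """Raised before any stage runs when the configuration is invalid."""


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for the composed pipelines."""

    input_path: Optional[Path] = None
    clips_dir: Optional[Path] = None
    events_path: Optional[Path] = None
    output_dir: Path = Path("lesioneval-out")
    sampling_interval_s: Optional[float] = None
    grid_start: float = 0.01
    grid_stop: float = 0.99
    grid_step: float = 0.01
    filter_window: int = 5
    filter_min_hits: int = 3
    fps: float = 30.0
    timeout_s: float = 5.0
    iou_cut: float = 0.5
    seed: int = 0
    latency_on_raw_hits: bool = False

    def __post_init__(self) -> None:
        if self.sampling_interval_s is not None and self.sampling_interval_s <= 0:
            raise ConfigError(
                f"sampling_interval_s must be positive, got {self.sampling_interval_s}"
            )
        if not (0.0 < self.grid_start <= self.grid_stop < 1.0):
            raise ConfigError(
                "threshold grid must satisfy 0 < start <= stop < 1, got "
                f"{self.grid_start}:{self.grid_stop}"
            )
        if self.grid_step <= 0:
            raise ConfigError(f"grid_step must be positive, got {self.grid_step}")
        if not (1 <= self.filter_min_hits <= self.filter_window):
            raise ConfigError(
                f"filter_min_hits must lie in [1, window], got "
                f"{self.filter_min_hits} of {self.filter_window}"
            )
        if self.fps <= 0:
            raise ConfigError(f"fps must be positive, got {self.fps}")
        if self.timeout_s < 0:
            raise ConfigError(f"timeout_s must be >= 0, got {self.timeout_s}")
        if not (0.0 <= self.iou_cut <= 1.0):
            raise ConfigError(f"iou_cut must lie in [0, 1], got {self.iou_cut}")

    def threshold_grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return np.round(self.grid_start + self.grid_step * np.arange(n), 10)


def _metric_cells(name: str, est: Optional[MetricEstimate]) -> dict:
    if est is None:
        return {
            f"{name}_pct": None,
            f"{name}_ci_low_pct": None,
            f"{name}_ci_high_pct": None,
        }
    return {
        f"{name}_pct": round(100 * est.value, 1),
        f"{name}_ci_low_pct": round(100 * est.ci_low, 1),
        f"{name}_ci_high_pct": round(100 * est.ci_high, 1),
    }


def report_rows_to_frame(rows: Sequence[StratumRow]) -> pd.DataFrame:
    """Render stratified report rows with Table-1-style column order."""
    records = []
    for row in rows:
        rec: dict = {
            "stratum": row.stratum,
            "n_positive": row.n_positive,
            "n_total": row.n_total,
            "prevalence_pct": round(100 * row.prevalence, 1),
            "youden_index": round(row.youden_j, 3),
            "threshold": row.threshold_label,
        }
        report = row.report
        rec.update(_metric_cells("sensitivity", report.sensitivity))
        rec.update(_metric_cells("specificity", report.specificity))
        rec.update(_metric_cells("ppv", report.ppv))
        rec.update(_metric_cells("npv", report.npv))
        rec.update(_metric_cells("accuracy", report.accuracy))
        if row.iou_ratio is None:
            rec.update({"iou50_pct": None, "iou50_num": None, "iou50_den": None})
        else:
            rec.update(
                {
                    "iou50_pct": round(row.iou_ratio.percentage, 1),
                    "iou50_num": row.iou_ratio.numerator,
                    "iou50_den": row.iou_ratio.denominator,
                }
            )
        records.append(rec)
    return pd.DataFrame.from_records(records)


def roc_points_to_frame(curve) -> pd.DataFrame:
    return pd.DataFrame.from_records(
        [
            {
                "threshold": p.threshold,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
                "youden_j": p.youden_j,
            }
            for p in curve.points
        ]
    )


def run_image_pipeline(config: RunConfig) -> dict:
    """Sample, exclude, evaluate, and report the image-based analysis.

    Writes ``report.csv``, ``roc_points.csv``, and ``summary.json`` under the
    configured output directory and returns the summary dictionary.
    """
    if config.input_path is None:
        raise ConfigError("input_path is required for the image pipeline")
    if not Path(config.input_path).exists():
        raise ConfigError(f"input file not found: {config.input_path}")

    frames = read_annotations(config.input_path)
    if config.sampling_interval_s is not None:
        from .frame_dataset import sample_frames

        frames = sample_frames(frames, config.sampling_interval_s)
    retained, tally = apply_exclusions(frames)
    for reason, count in sorted(tally.items(), key=lambda kv: kv[0].value):
        logger.info("excluded %d frames: %s", count, reason.value)
    logger.info("retained %d of %d frames", len(retained), len(frames))
    if not retained:
        raise ConfigError("no frames retained after exclusions")

    grid = config.threshold_grid()
    curve = roc_curve(retained, grid)
    rows = stratified_report(retained, grid, iou_cut=config.iou_cut)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report_frame = report_rows_to_frame(rows)
    report_frame.to_csv(out / "report.csv", index=False)
    roc_points_to_frame(curve).to_csv(out / "roc_points.csv", index=False)

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_input_frames": len(frames),
        "n_retained": len(retained),
        "exclusion_tally": {r.value: c for r, c in sorted(tally.items())},
        "auc": round(curve.auc, 3),
        "optimal_thresholds": list(curve.optimal_thresholds),
        "report": report_frame.to_dict(orient="records"),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    return summary


# --- detection-stream CSV i/o ---------------------------------------------

def write_stream_csv(stream: DetectionStream, path) -> None:
    n = len(stream)
    frame = pd.DataFrame(
        {
            "frame_index": np.arange(n),
            "timestamp": np.arange(n) / stream.fps,
            "hit": stream.hits.astype(int),
            "score": stream.scores if stream.scores is not None else np.zeros(n),
        }
    )
    frame.to_csv(path, index=False)


def read_stream_csv(path, case_id: str, fps: float) -> DetectionStream:
    frame = pd.read_csv(path)
    required = {"frame_index", "timestamp", "hit", "score"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigError(f"{path}: stream CSV missing columns {sorted(missing)}")
    frame = frame.sort_values("frame_index")
    return DetectionStream(
        case_id=case_id,
        fps=fps,
        hits=frame["hit"].to_numpy(dtype=bool),
        scores=frame["score"].to_numpy(dtype=float),
    )


def run_latency_pipeline(config: RunConfig) -> dict:
    """Filter clips, measure per-lesion latency, and summarize.

    Expects an events CSV (``lesion_id, case_id, paris_class, size_mm,
    appearance_frame, clip_file``) and the referenced per-clip stream CSVs
    under ``clips_dir``. Writes ``latency.csv`` and ``latency_summary.json``.
    """
    if config.events_path is None or config.clips_dir is None:
        raise ConfigError("events_path and clips_dir are required")
    if not Path(config.events_path).exists():
        raise ConfigError(f"events file not found: {config.events_path}")
    events_frame = pd.read_csv(config.events_path)
    required = {
        "lesion_id",
        "case_id",
        "paris_class",
        "size_mm",
        "appearance_frame",
        "clip_file",
    }
    missing = required - set(events_frame.columns)
    if missing:
        raise ConfigError(f"events CSV missing columns {sorted(missing)}")
    if events_frame.empty:
        raise ConfigError("events CSV contains no lesions")

    results = []
    records = []
    for row in events_frame.itertuples(index=False):
        clip_path = Path(config.clips_dir) / str(row.clip_file)
        if not clip_path.exists():
            raise ConfigError(f"clip file not found: {clip_path}")
        stream = read_stream_csv(clip_path, case_id=str(row.case_id), fps=config.fps)
        event = LesionEvent(
            lesion_id=str(row.lesion_id),
            case_id=str(row.case_id),
            paris_class=str(row.paris_class),
            size_mm=float(row.size_mm),
            appearance_frame=int(row.appearance_frame),
            clip=stream,
        )
        if config.latency_on_raw_hits:
            from .temporal_filter import DisplayStream

            display = DisplayStream(displayed=stream.hits)
        else:
            display = persistence_filter(
                stream, window=config.filter_window, min_hits=config.filter_min_hits
            )
        result = detection_latency(event, display, timeout_s=config.timeout_s)
        results.append(result)
        records.append(
            {
                "lesion_id": result.lesion_id,
                "case_id": event.case_id,
                "paris_class": event.paris_class,
                "size_mm": event.size_mm,
                "detected": result.detected,
                "latency_s": result.latency_s,
            }
        )

    summary_obj: LatencySummary = summarize_latencies(results)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame.from_records(records).to_csv(out / "latency.csv", index=False)
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "n_lesions": summary_obj.n_lesions,
        "n_detected": summary_obj.n_detected,
        "detection_rate_pct": round(summary_obj.detection_rate_pct, 1),
        "median_latency_s": summary_obj.median_latency_s,
        "min_latency_s": summary_obj.min_latency_s,
        "max_latency_s": summary_obj.max_latency_s,
    }
    (out / "latency_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    return summary
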