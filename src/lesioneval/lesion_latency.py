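"""Per-lesion detection latency under a failure timeout.

Latency runs from a lesion's expert-marked first appearance to the first
frame on which the (persistence-filtered) display stream fires; a lesion
with no display within the timeout counts as a detection failure.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

from .temporal_filter import DetectionStream, DisplayStream

__all__ = [
    "LesionEvent",
    "LatencyResult",
    "LatencySummary",
    "detection_latency",
    "summarize_latencies",
]


@dataclass(frozen=True)
class LesionEvent:
    """A lesion's first appearance inside a detection clip."""

    lesion_id: str
    case_id: str
    paris_class: str
    size_mm: float
    appearance_frame: int
    clip: DetectionStream

    def __post_init__(self) -> None:
        if self.size_mm <= 0:
            raise ValueError(f"size_mm must be positive, got {self.size_mm}")
        if not (0 <= self.appearance_frame < len(self.clip)):
            raise ValueError(
                f"appearance_frame {self.appearance_frame} outside clip of "
                f"{len(self.clip)} frames"
            )


@dataclass(frozen=True)
class LatencyResult:
    lesion_id: str
    detected: bool
    latency_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.detected != (self.latency_s is not None):
            raise ValueError("latency_s must be present iff detected")
        if self.latency_s is not None and self.latency_s < 0:
            raise ValueError(f"latency_s must be >= 0, got {self.latency_s}")


def detection_latency(
    event: LesionEvent, display: DisplayStream, timeout_s: float = 5.0
) -> LatencyResult:
    """First-display latency in seconds, or failure past the timeout.

    The display stream must align frame-for-frame with the event's clip.
    Detection counts only for displayed frames strictly less than
    ``timeout_s`` after the appearance frame, so a detected latency is
    always < timeout (with ``timeout_s=0`` every lesion fails).
    """
    if len(display) != len(event.clip):
        raise ValueError(
            f"display stream length {len(display)} does not match clip "
            f"length {len(event.clip)}"
        )
    if timeout_s < 0:
        raise ValueError(f"timeout_s must be >= 0, got {timeout_s}")
    fps = event.clip.fps
    for i in range(event.appearance_frame, len(display)):
        if (i - event.appearance_frame) / fps >= timeout_s:
            break
        if display.displayed[i]:
            latency = (i - event.appearance_frame) / fps
            return LatencyResult(
                lesion_id=event.lesion_id, detected=True, latency_s=latency
            )
    return LatencyResult(lesion_id=event.lesion_id, detected=False)


@dataclass(frozen=True)
class LatencySummary:
    n_lesions: int
    n_detected: int
    detection_rate_pct: float
    median_latency_s: Optional[float]
    min_latency_s: Optional[float]
    max_latency_s: Optional[float]


def summarize_latencies(results: Sequence[LatencyResult]) -> LatencySummary:
    """Detection rate over all lesions; median and range over detected only."""
    if not results:
        raise ValueError("results must be non-empty")
    detected = [r.latency_s for r in results if r.detected]
    rate = 100.0 * len(detected) / len(results)
    if detected:
        return LatencySummary(
            n_lesions=len(results),
            n_detected=len(detected),
            detection_rate_pct=rate,
            median_latency_s=statistics.median(detected),
            min_latency_s=min(detected),
            max_latency_s=max(detected),
        )
    return LatencySummary(
        n_lesions=len(results),
        n_detected=0,
        detection_rate_pct=rate,
        median_latency_s=None,
        min_latency_s=None,
        max_latency_s=None,
    )
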