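"""Annotation records, frame sampling, and exclusion rules.

A frame stream is a chronologically ordered list of :class:`FrameRecord`.
Streams are serialized as a single JSON document per case collection with a
mandatory ``schema_version`` field; boxes are ``[x_min, y_min, x_max, y_max]``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .geometry import BoundingBox

__all__ = [
    "ImagingMode",
    "ExclusionReason",
    "FrameRecord",
    "SCHEMA_VERSION",
    "sample_frames",
    "apply_exclusions",
    "read_annotations",
    "write_annotations",
]

SCHEMA_VERSION = "1.0"

#: Maximum ground-truth lesions per retained frame ("more than two" excluded).
MAX_LESIONS = 2


class ImagingMode(str, Enum):
    WLI = "WLI"
    CE = "CE"
    NBI = "NBI"
    OTHER = "OTHER"


class ExclusionReason(str, Enum):
    """Why a sampled frame is dropped before metric computation.

    The first five are human-provided labels carried on the record; only
    ``TOO_MANY_LESIONS`` is derivable from the annotations themselves.
    Enumeration order fixes the tally priority when several reasons apply.
    """

    OUTSIDE_COLORECTUM = "OUTSIDE_COLORECTUM"
    POST_RESECTION = "POST_RESECTION"
    OTHER_IMAGING_MODE = "OTHER_IMAGING_MODE"
    ARTIFICIAL_OBJECT = "ARTIFICIAL_OBJECT"
    SUBMUCOSAL_BLEB = "SUBMUCOSAL_BLEB"
    TOO_MANY_LESIONS = "TOO_MANY_LESIONS"


@dataclass
class FrameRecord:
    """One still image sampled from an annotated video stream."""

    case_id: str
    timestamp: float
    frame_index: int
    mode: ImagingMode
    exclusion_labels: frozenset = field(default_factory=frozenset)
    gt_boxes: list = field(default_factory=list)
    pred_boxes: list = field(default_factory=list)  # [(BoundingBox, score)]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        self.exclusion_labels = frozenset(
            ExclusionReason(r) for r in self.exclusion_labels
        )
        for _, score in self.pred_boxes:
            if not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"confidence score must lie in [0, 1], got {score} "
                    f"(case {self.case_id}, frame {self.frame_index})"
                )

    @property
    def lesion_positive(self) -> bool:
        return len(self.gt_boxes) > 0


def sample_frames(
    stream: Sequence[FrameRecord], interval: float, phase: float = 0.0
) -> list[FrameRecord]:
    """Pick the frame nearest each target time ``phase + k*interval``.

    Target times run from ``phase`` up to the last timestamp in the stream;
    ties between equally near frames go to the earlier one. The output is
    chronological and never selects the same frame twice.
    """
    if interval <= 0:
        raise ValueError(f"interval must be positive, got {interval}")
    if not stream:
        raise ValueError("stream must be non-empty")
    times = [f.timestamp for f in stream]
    end = times[-1]
    selected: list[int] = []
    seen: set[int] = set()
    t = phase
    # tolerate float accumulation at the stream end
    while t <= end + 1e-9:
        # nearest frame, ties to the earlier frame
        best = min(
            range(len(stream)),
            key=lambda i: (abs(times[i] - t), times[i]),
        )
        if best not in seen:
            seen.add(best)
            selected.append(best)
        t += interval
    selected.sort()
    return [stream[i] for i in selected]


def apply_exclusions(
    frames: Iterable[FrameRecord], max_lesions: int = MAX_LESIONS
) -> tuple[list[FrameRecord], Counter]:
    """Drop frames matching any exclusion rule; tally one reason per frame.

    A frame is retained iff it carries no exclusion labels, its imaging mode
    is not OTHER, and it shows at most ``max_lesions`` ground-truth lesions.
    Each excluded frame is counted once, under the first applicable reason in
    :class:`ExclusionReason` order, so ``len(retained) + sum(tally)`` equals
    the input size exactly.
    """
    retained: list[FrameRecord] = []
    tally: Counter = Counter()
    for frame in frames:
        reasons = set(frame.exclusion_labels)
        if frame.mode is ImagingMode.OTHER:
            reasons.add(ExclusionReason.OTHER_IMAGING_MODE)
        if len(frame.gt_boxes) > max_lesions:
            reasons.add(ExclusionReason.TOO_MANY_LESIONS)
        if reasons:
            first = min(reasons, key=list(ExclusionReason).index)
            tally[first] += 1
        else:
            retained.append(frame)
    return retained, tally


# --- serialization ---------------------------------------------------------

_FRAME_FIELDS = {
    "case_id",
    "timestamp",
    "frame_index",
    "mode",
    "exclusion_labels",
    "gt_boxes",
    "pred_boxes",
}


class AnnotationError(ValueError):
    """Raised when an annotation file violates the schema."""


def _frame_to_dict(frame: FrameRecord) -> dict:
    return {
        "case_id": frame.case_id,
        "timestamp": frame.timestamp,
        "frame_index": frame.frame_index,
        "mode": frame.mode.value,
        "exclusion_labels": sorted(r.value for r in frame.exclusion_labels),
        "gt_boxes": [b.to_list() for b in frame.gt_boxes],
        "pred_boxes": [[b.to_list(), s] for b, s in frame.pred_boxes],
    }


def _frame_from_dict(obj: dict, index: int) -> FrameRecord:
    unknown = set(obj) - _FRAME_FIELDS
    if unknown:
        raise AnnotationError(
            f"record {index}: unknown fields {sorted(unknown)}; "
            f"this reader supports schema version {SCHEMA_VERSION}"
        )
    missing = _FRAME_FIELDS - set(obj)
    if missing:
        raise AnnotationError(f"record {index}: missing fields {sorted(missing)}")
    try:
        return FrameRecord(
            case_id=str(obj["case_id"]),
            timestamp=float(obj["timestamp"]),
            frame_index=int(obj["frame_index"]),
            mode=ImagingMode(obj["mode"]),
            exclusion_labels=frozenset(
                ExclusionReason(r) for r in obj["exclusion_labels"]
            ),
            gt_boxes=[BoundingBox.from_list(b) for b in obj["gt_boxes"]],
            pred_boxes=[
                (BoundingBox.from_list(b), float(s)) for b, s in obj["pred_boxes"]
            ],
        )
    except (ValueError, TypeError) as exc:
        raise AnnotationError(f"record {index}: {exc}") from exc


def write_annotations(frames: Sequence[FrameRecord], path) -> None:
    """Write frames as a versioned JSON document."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "frames": [_frame_to_dict(f) for f in frames],
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_annotations(path) -> list[FrameRecord]:
    """Read frames back, validating the schema and stream invariants."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise AnnotationError(f"{path}: missing schema_version field")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise AnnotationError(
            f"{path}: schema version {doc['schema_version']!r} unsupported; "
            f"this reader supports {SCHEMA_VERSION}"
        )
    unknown = set(doc) - {"schema_version", "frames"}
    if unknown:
        raise AnnotationError(f"{path}: unknown top-level fields {sorted(unknown)}")
    frames = [_frame_from_dict(o, i) for i, o in enumerate(doc.get("frames", []))]
    _check_stream_order(frames)
    return frames


def _check_stream_order(frames: Sequence[FrameRecord]) -> None:
    last: dict[str, tuple[int, float]] = {}
    for i, frame in enumerate(frames):
        prev = last.get(frame.case_id)
        if prev is not None:
            pidx, pts = prev
            if frame.frame_index > pidx and frame.timestamp <= pts:
                raise AnnotationError(
                    f"record {i}: timestamps not strictly increasing with "
                    f"frame_index in case {frame.case_id!r}"
                )
        last[frame.case_id] = (frame.frame_index, frame.timestamp)
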