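"""Axis-aligned bounding boxes and intersection-over-union.

Boxes use half-open pixel intervals ``[x_min, x_max) x [y_min, y_max)``
with the origin at the image top-left, so the area of an integer-coordinate
box equals the number of pixel cells it covers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = ["BoundingBox", "MatchResult", "iou", "best_match"]


@dataclass(frozen=True)
class BoundingBox:
    """An axis-aligned rectangle in pixel coordinates.

    Parameters
    ----------
    x_min, y_min, x_max, y_max
        Corners of the half-open rectangle. Must satisfy
        ``x_max > x_min``, ``y_max > y_min``, and all coordinates must be
        finite and non-negative.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise ValueError(f"box coordinates must be finite, got {coords}")
        if any(c < 0 for c in coords):
            raise ValueError(f"box coordinates must be non-negative, got {coords}")
        if self.x_max <= self.x_min or self.y_max <= self.y_min:
            raise ValueError(
                f"box must have strictly positive area, got {coords}"
            )

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def to_list(self) -> list:
        """Serialize as ``[x_min, y_min, x_max, y_max]``."""
        return [self.x_min, self.y_min, self.x_max, self.y_max]

    @classmethod
    def from_list(cls, values: Sequence[float]) -> "BoundingBox":
        if len(values) != 4:
            raise ValueError(f"expected 4 coordinates, got {len(values)}")
        return cls(*map(float, values))


@dataclass(frozen=True)
class MatchResult:
    """Best predicted-box match for one ground-truth box.

    ``pred_index`` is ``None`` when no predicted box was available; in that
    case ``iou`` is 0.
    """

    gt_index: int
    pred_index: Optional[int]
    iou: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.iou <= 1.0):
            raise ValueError(f"iou must lie in [0, 1], got {self.iou}")
        if self.pred_index is None and self.iou != 0.0:
            raise ValueError("iou must be 0 when no predicted box matches")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes.

    Returns ``|a ∩ b| / |a ∪ b|`` computed from rectangle areas; symmetric
    in its arguments and exactly 1.0 for identical boxes.
    """
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def best_match(
    gt_boxes: Sequence[BoundingBox], pred_boxes: Sequence[BoundingBox]
) -> list[MatchResult]:
    """Match each ground-truth box to the predicted box of maximal IoU.

    Ties are broken toward the lowest predicted-box index; matching is not
    one-to-one (two ground-truth boxes may claim the same prediction). With
    no predictions every result carries ``pred_index=None`` and ``iou=0``.
    """
    if not gt_boxes:
        raise ValueError("gt_boxes must be non-empty")
    results: list[MatchResult] = []
    for gi, gt in enumerate(gt_boxes):
        best_idx: Optional[int] = None
        best_iou = 0.0
        for pi, pred in enumerate(pred_boxes):
            value = iou(gt, pred)
            if best_idx is None or value > best_iou:
                best_idx, best_iou = pi, value
        if best_idx is None:
            results.append(MatchResult(gt_index=gi, pred_index=None, iou=0.0))
        else:
            results.append(MatchResult(gt_index=gi, pred_index=best_idx, iou=best_iou))
    return results
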