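"""Display-side persistence filtering of per-frame detections.

A detection is displayed only when raw detections occur in at least
``min_hits`` of the last ``window`` frames (current frame plus the
``window - 1`` preceding ones, padded with misses before stream start).
The defaults, 3 of 5, suppress single-frame flicker false positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "DetectionStream",
    "DisplayStream",
    "persistence_filter",
    "filter_equivalence_oracle",
]


@dataclass(frozen=True)
class DetectionStream:
    """Raw per-frame detection flags for one video clip."""

    case_id: str
    fps: float
    hits: np.ndarray
    scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "hits", np.asarray(self.hits, dtype=bool))
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if self.hits.size < 1:
            raise ValueError("hits must contain at least one frame")
        if self.scores is not None:
            scores = np.asarray(self.scores, dtype=float)
            if scores.shape != self.hits.shape:
                raise ValueError("scores must align frame-for-frame with hits")
            object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return int(self.hits.size)


@dataclass(frozen=True)
class DisplayStream:
    """Filtered per-frame display flags, aligned with the source stream."""

    displayed: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "displayed", np.asarray(self.displayed, dtype=bool))

    def __len__(self) -> int:
        return int(self.displayed.size)


def persistence_filter(
    stream: DetectionStream, window: int = 5, min_hits: int = 3
) -> DisplayStream:
    """Causal m-of-n filter over the raw hit sequence.

    ``displayed[i]`` is true iff frames ``max(0, i-window+1) .. i`` contain at
    least ``min_hits`` raw hits; frames before the stream start count as
    misses.
    """
    _validate_rule(window, min_hits)
    hits = stream.hits.astype(np.int64)
    csum = np.concatenate([[0], np.cumsum(hits)])
    idx = np.arange(hits.size)
    start = np.maximum(0, idx - window + 1)
    in_window = csum[idx + 1] - csum[start]
    return DisplayStream(displayed=in_window >= min_hits)


def filter_equivalence_oracle(
    hits: Sequence[bool], window: int = 5, min_hits: int = 3
) -> DisplayStream:
    """Brute-force reference: count hits in every causal window explicitly."""
    _validate_rule(window, min_hits)
    hits = [bool(h) for h in hits]
    displayed = []
    for i in range(len(hits)):
        count = sum(hits[max(0, i - window + 1) : i + 1])
        displayed.append(count >= min_hits)
    return DisplayStream(displayed=np.array(displayed, dtype=bool))


def _validate_rule(window: int, min_hits: int) -> None:
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if not (1 <= min_hits <= window):
        raise ValueError(
            f"min_hits must lie in [1, window], got min_hits={min_hits}, "
            f"window={window}"
        )
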