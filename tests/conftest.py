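import numpy as np
import pytest

from lesioneval import BoundingBox, FrameRecord, ImagingMode


def make_frame(
    frame_index,
    gt=(),
    preds=(),
    mode=ImagingMode.WLI,
    case_id="case-1",
    timestamp=None,
    labels=(),
):
    """Compact FrameRecord factory for tests.

    ``gt`` is a sequence of box coordinate 4-tuples; ``preds`` a sequence of
    (box 4-tuple, score) pairs.
    """
    return FrameRecord(
        case_id=case_id,
        timestamp=float(frame_index) if timestamp is None else timestamp,
        frame_index=frame_index,
        mode=mode,
        exclusion_labels=frozenset(labels),
        gt_boxes=[BoundingBox(*b) for b in gt],
        pred_boxes=[(BoundingBox(*b), s) for b, s in preds],
    )


GT_BOX = (100.0, 100.0, 200.0, 200.0)


def scored_frames(pos_scores, neg_scores):
    """Frames with one gt box per positive; scores become single pred boxes.

    A score of None means no predicted box at all.
    """
    frames = []
    idx = 0
    for s in pos_scores:
        preds = [] if s is None else [(GT_BOX, s)]
        frames.append(make_frame(idx, gt=[GT_BOX], preds=preds))
        idx += 1
    for s in neg_scores:
        preds = [] if s is None else [(GT_BOX, s)]
        frames.append(make_frame(idx, preds=preds))
        idx += 1
    return frames


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
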