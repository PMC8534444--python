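import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import binom

from lesioneval import (
    ConfusionCounts,
    classify_image,
    clopper_pearson,
    confusion_at_threshold,
    diagnostic_metrics,
    image_score,
    iou50_ratio,
    roc_curve,
    youden_optimal,
)
from lesioneval.image_metrics import default_threshold_grid, format_threshold_range

from conftest import GT_BOX, make_frame, scored_frames


def cp_tail_sum_oracle(k, n, level=0.95):
    """Independent Clopper-Pearson oracle by root-finding on binomial tails."""
    alpha = 1 - level
    lower = 0.0 if k == 0 else brentq(
        lambda p: binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    upper = 1.0 if k == n else brentq(
        lambda p: binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12, xtol=1e-12
    )
    return lower, upper


def rank_auc_oracle(pos_scores, neg_scores):
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    pos = np.asarray(pos_scores)[:, None]
    neg = np.asarray(neg_scores)[None, :]
    return float(((pos > neg).mean() + 0.5 * (pos == neg).mean()))


class TestImageScore:
    def test_no_boxes(self):
        assert image_score(make_frame(0)) == 0.0

    def test_maximum(self):
        frame = make_frame(0, preds=[(GT_BOX, 0.2), (GT_BOX, 0.9)])
        assert image_score(frame) == 0.9

    def test_singleton(self):
        assert image_score(make_frame(0, preds=[(GT_BOX, 0.27)])) == 0.27


class TestClassifyImage:
    @pytest.mark.parametrize(
        "gt,pred,label",
        [(True, True, "TP"), (False, False, "TN"), (False, True, "FP"), (True, False, "FN")],
    )
    def test_table(self, gt, pred, label):
        assert classify_image(gt, pred) == label

    def test_disjoint_boxes_still_tp(self):
        # overlap is irrelevant at the image level
        frame = make_frame(0, gt=[GT_BOX], preds=[((500.0, 500.0, 600.0, 600.0), 0.9)])
        counts = confusion_at_threshold([frame], 0.5)
        assert counts.n_tp == 1

    def test_multiple_fp_boxes_count_once(self):
        frame = make_frame(
            0, preds=[((0.0, 0.0, 10.0, 10.0), 0.8), ((20.0, 20.0, 30.0, 30.0), 0.9)]
        )
        counts = confusion_at_threshold([frame], 0.5)
        assert counts.n_fp == 1 and counts.total == 1


class TestConfusionAtThreshold:
    def test_all_negative_no_boxes(self):
        frames = scored_frames([], [None] * 7)
        counts = confusion_at_threshold(frames, 0.27)
        assert (counts.n_tp, counts.n_fn, counts.n_fp, counts.n_tn) == (0, 0, 0, 7)

    def test_threshold_above_all_scores(self):
        frames = scored_frames([0.3, 0.5], [0.2, 0.4])
        counts = confusion_at_threshold(frames, 0.9)
        assert counts.n_tp == 0 and counts.n_fp == 0

    def test_hand_counted_fixture(self):
        # hand count at t=0.5: positives scoring {0.9,0.6,0.5}->TP, {0.4,None}->FN;
        # negatives scoring {0.7,0.5}->FP, {0.3,0.1,None}->TN
        frames = scored_frames([0.9, 0.6, 0.5, 0.4, None], [0.7, 0.5, 0.3, 0.1, None])
        counts = confusion_at_threshold(frames, 0.5)
        assert (counts.n_tp, counts.n_fn, counts.n_fp, counts.n_tn) == (3, 2, 2, 3)

    @given(
        pos=st.lists(st.one_of(st.none(), st.floats(0, 1)), max_size=20),
        neg=st.lists(st.one_of(st.none(), st.floats(0, 1)), max_size=20),
        t1=st.floats(0.01, 0.99),
        t2=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_and_monotonicity(self, pos, neg, t1, t2):
        frames = scored_frames(pos, neg)
        lo, hi = sorted((t1, t2))
        c_lo = confusion_at_threshold(frames, lo)
        c_hi = confusion_at_threshold(frames, hi)
        assert c_lo.total == c_hi.total == len(frames)
        assert c_hi.n_tp <= c_lo.n_tp
        assert c_hi.n_fp <= c_lo.n_fp


class TestClopperPearson:
    def test_printed_interval(self):
        lower, upper = clopper_pearson(626, 662)
        assert round(100 * lower, 1) == 92.6
        assert round(100 * upper, 1) == 96.2

    def test_boundaries(self):
        assert clopper_pearson(0, 20)[0] == 0.0
        assert clopper_pearson(20, 20)[1] == 1.0

    @pytest.mark.parametrize("k,n", [(0, 5), (5, 5), (1, 10), (626, 662), (331, 662)])
    def test_against_tail_sum_oracle(self, k, n):
        got = clopper_pearson(k, n)
        want = cp_tail_sum_oracle(k, n)
        assert got == pytest.approx(want, abs=1e-9)

    @given(n=st.integers(1, 200), frac=st.floats(0, 1))
    @settings(max_examples=100, deadline=None)
    def test_contains_point_estimate(self, n, frac):
        k = int(round(frac * n))
        lower, upper = clopper_pearson(k, n)
        assert lower <= k / n <= upper

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestDiagnosticMetrics:
    def test_overall_sensitivity(self):
        report = diagnostic_metrics(ConfusionCounts(n_tp=626, n_fn=36, n_fp=0, n_tn=1))
        assert round(100 * report.sensitivity.value, 1) == 94.6

    def test_ce_sensitivity(self):
        report = diagnostic_metrics(ConfusionCounts(n_tp=173, n_fn=9, n_fp=0, n_tn=1))
        assert round(100 * report.sensitivity.value, 1) == 95.1

    def test_symmetric_counts(self):
        report = diagnostic_metrics(ConfusionCounts(1, 1, 1, 1))
        for est in (
            report.sensitivity,
            report.specificity,
            report.ppv,
            report.npv,
            report.accuracy,
        ):
            assert est.value == 0.5

    def test_accuracy_exact(self):
        counts = ConfusionCounts(n_tp=3, n_fn=2, n_fp=1, n_tn=4)
        report = diagnostic_metrics(counts)
        assert report.accuracy.value == (3 + 4) / 10

    def test_zero_denominator_reported_as_missing(self):
        report = diagnostic_metrics(ConfusionCounts(n_tp=0, n_fn=0, n_fp=0, n_tn=5))
        assert report.sensitivity is None
        assert report.ppv is None
        assert report.specificity.value == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            diagnostic_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_point_estimates_inside_cis(self):
        report = diagnostic_metrics(ConfusionCounts(n_tp=626, n_fn=36, n_fp=287, n_tn=5582))
        for est in (
            report.sensitivity,
            report.specificity,
            report.ppv,
            report.npv,
            report.accuracy,
        ):
            assert est.ci_low <= est.value <= est.ci_high


class TestROC:
    def test_grid(self):
        grid = default_threshold_grid()
        assert len(grid) == 99
        assert grid[0] == 0.01 and grid[-1] == 0.99

    def test_perfect_separation(self):
        frames = scored_frames([0.9] * 5, [0.1] * 5)
        assert roc_curve(frames).auc == 1.0

    def test_degenerate_identical_scores(self):
        frames = scored_frames([0.5] * 5, [0.5] * 5)
        assert roc_curve(frames).auc == pytest.approx(0.5)

    def test_auc_matches_rank_oracle(self, rng):
        pos = rng.beta(4, 1, size=100)
        neg = rng.beta(1, 4, size=100)
        frames = scored_frames(pos, neg)
        curve = roc_curve(frames)
        assert curve.auc == pytest.approx(rank_auc_oracle(pos, neg), abs=0.01)

    def test_monotone_points(self, rng):
        frames = scored_frames(rng.beta(4, 1, 50), rng.beta(1, 4, 50))
        points = roc_curve(frames).points
        sens = [p.sensitivity for p in points]
        spec = [p.specificity for p in points]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(scored_frames([0.9], []))


class TestYouden:
    def test_unique_maximum(self):
        # positives at >=0.27, negatives strictly below: J=1 only on (0.25, 0.27]
        frames = scored_frames([0.27, 0.4, 0.9], [0.25, 0.1, 0.05])
        curve = roc_curve(frames)
        assert 0.27 in curve.optimal_thresholds
        assert all(0.25 < t <= 0.27 for t in curve.optimal_thresholds)
        # exhaustive scan over the grid agrees
        best = max(p.youden_j for p in curve.points)
        expected = {p.threshold for p in curve.points if p.youden_j == best}
        assert set(youden_optimal(curve)) == expected

    def test_contiguous_tie_formatting(self):
        # no score falls inside [0.05, 0.06), so both thresholds give equal counts
        frames = scored_frames([0.06, 0.9], [0.04, 0.01])
        curve = roc_curve(frames)
        ties = youden_optimal(curve)
        assert 0.05 in ties and 0.06 in ties
        assert format_threshold_range([0.05, 0.06]) == "0.05-0.06"
        assert format_threshold_range([0.27]) == "0.27"

    def test_single_positive_isolation(self):
        frames = scored_frames([0.8], [0.3, 0.2, 0.1])
        curve = roc_curve(frames)
        assert all(0.3 < t <= 0.8 for t in youden_optimal(curve))


class TestIoU50Ratio:
    def test_all_identical_boxes(self):
        frames = [make_frame(i, gt=[GT_BOX], preds=[(GT_BOX, 0.9)]) for i in range(5)]
        result = iou50_ratio(frames, 0.5)
        assert result.percentage == 100.0

    def test_all_disjoint_boxes(self):
        off = (500.0, 500.0, 600.0, 600.0)
        frames = [make_frame(i, gt=[GT_BOX], preds=[(off, 0.9)]) for i in range(5)]
        assert iou50_ratio(frames, 0.5).percentage == 0.0

    def test_printed_ratio(self):
        off = (500.0, 500.0, 600.0, 600.0)
        frames = [make_frame(i, gt=[GT_BOX], preds=[(GT_BOX, 0.9)]) for i in range(609)]
        frames += [
            make_frame(609 + i, gt=[GT_BOX], preds=[(off, 0.9)]) for i in range(17)
        ]
        result = iou50_ratio(frames, 0.27)
        assert result.numerator == 609 and result.denominator == 626
        assert round(result.percentage, 1) == 97.3

    def test_boundary_is_inclusive_by_default(self):
        # side 192 shifted by 64 (one third): IoU is exactly 24576/49152 = 0.5
        gt = (0.0, 0.0, 192.0, 192.0)
        shifted = (64.0, 0.0, 256.0, 192.0)
        frame = make_frame(0, gt=[gt], preds=[(shifted, 0.9)])
        assert iou50_ratio([frame], 0.5).numerator == 1
        assert iou50_ratio([frame], 0.5, strict=True).numerator == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            iou50_ratio([], 0.5)

    def test_non_tp_frame_rejected(self):
        with pytest.raises(ValueError):
            iou50_ratio([make_frame(0, gt=[GT_BOX])], 0.5)
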