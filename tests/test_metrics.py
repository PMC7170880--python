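"""Confusion metrics, ROC/AUROC, operating points, seed aggregation.

The brute-force oracles here count pairs and confusion cells directly and
never share code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from weakeeg.errors import (
    InsufficientReplicatesError,
    NoFeasibleThresholdError,
    UndefinedMetricError,
)
from weakeeg.metrics import (
    aggregate_over_seeds,
    confusion_metrics,
    evaluate_probs,
    median_roc,
    operating_point,
    roc_auroc,
)


def _auroc_by_pair_counting(labels, probs):
    pos = [p for l, p in zip(labels, probs) if l == 1]
    neg = [p for l, p in zip(labels, probs) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _confusion_by_counting(labels, probs, thr):
    tp = sum(1 for l, p in zip(labels, probs) if l == 1 and p >= thr)
    fp = sum(1 for l, p in zip(labels, probs) if l == 0 and p >= thr)
    fn = sum(1 for l, p in zip(labels, probs) if l == 1 and p < thr)
    tn = sum(1 for l, p in zip(labels, probs) if l == 0 and p < thr)
    return tp, fp, tn, fn


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        r = confusion_metrics([1, 0], [0.9, 0.1])
        assert (r.precision, r.recall, r.f1, r.fpr) == (1.0, 1.0, 1.0, 0.0)

    def test_symmetric_half_case(self):
        # precision = recall = 0.5 -> F1 = 0.5 by the harmonic-mean formula
        r = confusion_metrics([1, 1, 0, 0], [0.9, 0.1, 0.8, 0.2])
        assert (r.precision, r.recall, r.f1) == (0.5, 0.5, 0.5)

    def test_hand_evaluated_counts(self):
        # TP=3 FP=1 FN=2 TN=4 -> precision .75, recall .6, F1 2/3, FPR .2
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        probs = [0.9, 0.8, 0.7, 0.2, 0.1, 0.6, 0.3, 0.2, 0.1, 0.05]
        r = confusion_metrics(labels, probs, threshold=0.5)
        assert (r.counts.tp, r.counts.fp, r.counts.fn, r.counts.tn) == (3, 1, 2, 4)
        assert r.precision == 0.75
        assert r.recall == pytest.approx(0.6)
        assert r.f1 == pytest.approx(2 / 3)
        assert r.fpr == pytest.approx(0.2)

    def test_zero_denominator_conventions(self):
        none_predicted = confusion_metrics([0, 0], [0.1, 0.2])
        assert (none_predicted.precision, none_predicted.recall, none_predicted.f1) == (0, 0, 0)
        all_negative = confusion_metrics([1, 1], [0.9, 0.8])
        assert all_negative.fpr == 0.0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [0.5])
        with pytest.raises(ValueError):
            confusion_metrics([1, 2], [0.5, 0.5])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)),
                    min_size=1, max_size=20),
           st.floats(0.05, 0.95))
    def test_matches_direct_counting_on_random_instances(self, pairs, thr):
        labels = [l for l, _ in pairs]
        probs = [round(p, 3) for _, p in pairs]
        tp, fp, tn, fn = _confusion_by_counting(labels, probs, thr)
        r = confusion_metrics(labels, probs, thr)
        assert (r.counts.tp, r.counts.fp, r.counts.tn, r.counts.fn) == (tp, fp, tn, fn)
        assert r.precision == (tp / (tp + fp) if tp + fp else 0.0)
        assert r.recall == (tp / (tp + fn) if tp + fn else 0.0)
        expected_f1 = (2 * r.precision * r.recall / (r.precision + r.recall)
                       if r.precision + r.recall else 0.0)
        assert r.f1 == pytest.approx(expected_f1)
        assert r.fpr == (fp / (fp + tn) if fp + tn else 0.0)


class TestROC:
    def test_separated_scores_reach_one(self):
        _, auroc = roc_auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auroc == 1.0

    def test_four_clip_example_by_pair_counting(self):
        labels, probs = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]
        _, auroc = roc_auroc(labels, probs)
        assert auroc == 0.75 == _auroc_by_pair_counting(labels, probs)

    def test_all_ties_give_half(self):
        _, auroc = roc_auroc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auroc == 0.5

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            roc_auroc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_curve_is_monotone_with_unit_endpoints(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        probs = rng.random(50)
        (fpr, tpr, _), _ = roc_auroc(labels, probs)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)
        assert (fpr[0], tpr[0]) == (0.0, 0.0) and (fpr[-1], tpr[-1]) == (1.0, 1.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.tuples(st.integers(0, 1), st.floats(0, 1)),
                    min_size=2, max_size=20).filter(
               lambda ps: len({l for l, _ in ps}) == 2))
    def test_matches_pair_counting_on_random_instances(self, pairs):
        labels = [l for l, _ in pairs]
        probs = [round(p, 2) for _, p in pairs]  # coarse grid forces ties
        _, auroc = roc_auroc(labels, probs)
        assert auroc == pytest.approx(_auroc_by_pair_counting(labels, probs))


class TestOperatingPoint:
    def test_perfect_classifier_dominant_point(self):
        roc, _ = roc_auroc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        thr, tpr, fpr = operating_point(roc, target_tpr=0.9)
        assert (tpr, fpr) == (1.0, 0.0)

    def test_zero_fpr_boundary(self):
        roc, _ = roc_auroc([1, 0], [0.3, 0.9])  # only FPR=0 point has TPR=0
        thr, tpr, fpr = operating_point(roc, target_fpr=0.0)
        assert fpr == 0.0 and tpr == 0.0

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        probs = np.round(rng.random(30), 2)
        roc, _ = roc_auroc(labels, probs)
        for target in (0.5, 0.8, 1.0):
            thr, tpr, fpr = operating_point(roc, target_tpr=target)
            # brute force over every candidate threshold
            best = None
            for t in np.unique(np.concatenate([probs, [np.inf]])):
                tp, fp, tn, fn = _confusion_by_counting(labels, probs, t)
                cur_tpr = tp / (tp + fn)
                cur_fpr = fp / (fp + tn)
                if cur_tpr >= target and (best is None or t > best[0]):
                    best = (t, cur_tpr, cur_fpr)
            assert tpr == pytest.approx(best[1]) and fpr == pytest.approx(best[2])

    def test_unreachable_target_raises(self):
        roc, _ = roc_auroc([0, 1], [0.2, 0.8])
        with pytest.raises(NoFeasibleThresholdError):
            operating_point(roc, target_tpr=1.5)
        with pytest.raises(ValueError):
            operating_point(roc)


class TestSeedAggregation:
    def test_degenerate_replicates_have_zero_width(self):
        agg = aggregate_over_seeds([0.8] * 5)
        assert agg.mean == 0.8 and agg.ci_width == 0.0

    def test_median_is_the_order_statistic(self):
        assert aggregate_over_seeds([0.7, 0.8, 0.9]).median == 0.8

    def test_t_interval_matches_closed_form(self):
        # mean 0.8, s = sqrt(0.025), t(0.975, 4) = 2.7764
        agg = aggregate_over_seeds([0.6, 0.7, 0.8, 0.9, 1.0])
        half = 2.7764451052 * np.sqrt(0.025) / np.sqrt(5)
        assert agg.mean == pytest.approx(0.8)
        assert agg.ci_low == pytest.approx(0.8 - half, abs=1e-9)
        assert agg.ci_high == pytest.approx(0.8 + half, abs=1e-9)

    def test_single_value_rejected(self):
        with pytest.raises(InsufficientReplicatesError):
            aggregate_over_seeds([0.8])


class TestMedianROC:
    def test_identical_curves_are_their_own_median(self):
        roc, _ = roc_auroc([0, 1, 0, 1], [0.2, 0.9, 0.4, 0.7])
        grid, med = median_roc([roc, roc, roc])
        assert len(grid) == 101
        assert np.allclose(med, np.interp(grid, roc[0], roc[1]))


def test_full_report_combines_threshold_and_ranking_views():
    labels = [1, 0, 1, 0, 1, 0]
    probs = [0.9, 0.2, 0.6, 0.4, 0.3, 0.1]
    report = evaluate_probs(labels, probs, threshold=0.5)
    assert report.auroc == pytest.approx(_auroc_by_pair_counting(labels, probs))
    assert report.counts.total == 6
    assert report.roc is not None
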