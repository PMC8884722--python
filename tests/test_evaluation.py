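"""ROC/AUC, cutpoints, aggregation, frequent features, and relative risk."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prernadx.evaluation import (
    EvaluationError,
    aggregate_repeats,
    frequent_features,
    leave_out_eval,
    optimal_cutpoint,
    relative_risk,
    roc_auc,
    threshold_metrics,
)
from prernadx.ml import FitResult


def brute_force_auc(scores, labels):
    """Pairwise concordance over all case-control pairs, ties credited 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert res.auc == 1.0

    def test_full_ties_give_half(self):
        res = roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0])
        assert res.auc == 0.5

    def test_worked_example_three_quarters(self):
        res = roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0])
        assert res.auc == pytest.approx(0.75)
        assert res.auc == pytest.approx(
            brute_force_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]))

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(200):
            n = rng.integers(4, 51)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(0, 1, n), 2)  # induce ties
            res = roc_auc(scores, labels)
            assert res.auc == pytest.approx(brute_force_auc(scores, labels),
                                            abs=1e-12)

    def test_complement_symmetry_without_ties(self, rng):
        scores = rng.permutation(np.linspace(0.01, 0.99, 30))
        labels = (rng.uniform(size=30) > 0.5).astype(int)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels).auc + roc_auc(-scores, labels).auc \
            == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.99), min_size=4, max_size=20))
    def test_monotone_transform_invariance(self, raw):
        # round so the strictly monotone map cannot merge near-equal
        # floats into new ties
        scores = np.round(np.asarray(raw), 3)
        labels = (np.arange(len(scores)) % 2).astype(int)
        a = roc_auc(scores, labels).auc
        b = roc_auc(np.exp(3 * scores), labels).auc
        assert a == pytest.approx(b)

    def test_trapezoid_area_equals_auc(self, rng):
        scores = np.round(rng.uniform(size=40), 1)
        labels = (rng.uniform(size=40) > 0.4).astype(int)
        labels[:2] = [0, 1]
        res = roc_auc(scores, labels)
        fpr, tpr = zip(*res.roc_points)
        assert np.trapezoid(tpr, fpr) == pytest.approx(res.auc)

    def test_roc_points_monotone_from_origin_to_one(self, rng):
        scores = rng.uniform(size=25)
        labels = (rng.uniform(size=25) > 0.5).astype(int)
        labels[:2] = [0, 1]
        pts = roc_auc(scores, labels).roc_points
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        fpr, tpr = zip(*pts)
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_single_class_errors(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestThresholdMetrics:
    def test_boundary_thresholds(self):
        scores = [0.2, 0.4, 0.6, 0.8]
        labels = [0, 0, 1, 1]
        assert threshold_metrics(scores, labels, 0.0) == (0.5, 1.0, 0.0)
        _, sn, sp = threshold_metrics(scores, labels, 0.9)
        assert (sn, sp) == (0.0, 1.0)

    def test_worked_four_sample_table(self):
        """Scores (0.9,0.8,0.3,0.2), labels (1,0,1,0) at t=0.5:
        TP=1, FP=1, FN=1, TN=1 -> acc .5, sn .5, sp .5."""
        acc, sn, sp = threshold_metrics([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0], 0.5)
        assert (acc, sn, sp) == (0.5, 0.5, 0.5)

    def test_single_class_errors(self):
        with pytest.raises(EvaluationError):
            threshold_metrics([0.5], [1], 0.5)


class TestOptimalCutpoint:
    def test_separated_scores_give_gap_midpoint(self):
        thr = optimal_cutpoint([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert thr == pytest.approx(0.5)
        _, sn, sp = threshold_metrics([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], thr)
        assert sn + sp - 1 == pytest.approx(1.0)

    def test_tie_breaks_to_lowest_threshold(self):
        # J identical at 0.3 and 0.5; the lower wins
        thr = optimal_cutpoint([0.2, 0.4, 0.4, 0.6], [0, 1, 0, 1])
        assert thr == pytest.approx(0.3)

    def test_all_equal_scores_error(self):
        with pytest.raises(EvaluationError):
            optimal_cutpoint([0.5, 0.5], [0, 1])

    def test_anti_separated_warns(self):
        with pytest.warns(UserWarning, match="Youden"):
            optimal_cutpoint([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1])


class TestAggregateRepeats:
    def test_frozen_t_interval(self):
        """(0.70,0.72,0.68,0.71,0.69) -> mean .700, 95% CI (.680, .720)."""
        agg = aggregate_repeats([0.70, 0.72, 0.68, 0.71, 0.69])
        assert agg.mean_auc == pytest.approx(0.700, abs=5e-4)
        assert agg.ci_low == pytest.approx(0.680, abs=5e-4)
        assert agg.ci_high == pytest.approx(0.720, abs=5e-4)

    def test_identical_values_zero_width(self):
        agg = aggregate_repeats([0.8, 0.8, 0.8])
        assert agg.ci_low == pytest.approx(0.8, abs=1e-12)
        assert agg.mean_auc == pytest.approx(0.8, abs=1e-12)
        assert agg.ci_high == pytest.approx(0.8, abs=1e-12)

    def test_translation_equivariance(self):
        a = aggregate_repeats([0.6, 0.65, 0.7])
        b = aggregate_repeats([0.7, 0.75, 0.8])
        assert b.mean_auc - a.mean_auc == pytest.approx(0.1)
        assert b.ci_low - a.ci_low == pytest.approx(0.1)

    def test_single_value_errors(self):
        with pytest.raises(EvaluationError):
            aggregate_repeats([0.7])


def fit_with(features):
    return FitResult(model_kind="lasso", hyperparams={}, cv_auc=0.8,
                     model=None, nonzero_features=features)


class TestFrequentFeatures:
    def test_always_selected_feature_ranks_first(self):
        fits = [fit_with([("stable", 1.0), (f"rare{i}", 9.0)])
                for i in range(5)]
        top = frequent_features(fits, top_n=3, min_repeats=3)
        assert top[0].feature_id == "stable"
        assert top[0].frequency == 1.0

    def test_min_repeats_filters(self):
        fits = [fit_with([("a", 1.0)]), fit_with([("a", 1.0)]),
                fit_with([("b", 5.0)])]
        top = frequent_features(fits, top_n=5, min_repeats=2)
        assert [p.feature_id for p in top] == ["a"]

    def test_tie_broken_by_importance_then_id(self):
        fits = [fit_with([("hi", 2.0), ("lo", 1.0), ("aa", 1.0)])] * 3
        top = frequent_features(fits, top_n=3, min_repeats=3)
        assert [p.feature_id for p in top] == ["hi", "aa", "lo"]

    def test_nothing_frequent_errors(self):
        with pytest.raises(EvaluationError):
            frequent_features([fit_with([("a", 1.0)])], min_repeats=2)


class TestLeaveOutEval:
    def test_empty_leave_out_gives_identical_results(self):
        scores = [0.9, 0.2, 0.8, 0.1]
        labels = [1, 0, 1, 0]
        a, b = leave_out_eval(scores, labels, [], [],
                              train_ids=["t1"], test_ids=["s1", "s2"],
                              leave_out_ids=[])
        assert a.auc == b.auc and a.accuracy == b.accuracy

    def test_overlap_with_training_is_fatal(self):
        with pytest.raises(EvaluationError, match="t1"):
            leave_out_eval([0.9, 0.1], [1, 0], [0.5], [0],
                           train_ids=["t1", "t2"], test_ids=["s1", "s2"],
                           leave_out_ids=["t1"])

    def test_null_leave_out_controls_dilute_auc(self, rng):
        """Adding label-0 samples with uninformative scores drags the
        combined AUC toward chance, mirroring non-smoker inclusion."""
        drops = 0
        for _ in range(20):
            te_s = np.concatenate([rng.uniform(0.5, 1, 30),
                                   rng.uniform(0, 0.5, 30)])
            te_l = np.repeat([1, 0], 30)
            lo_s = rng.uniform(0, 1, 60)
            lo_l = np.zeros(60, dtype=int)
            a, b = leave_out_eval(te_s, te_l, lo_s, lo_l,
                                  train_ids=["x"], test_ids=["y"],
                                  leave_out_ids=["z"])
            drops += b.auc <= a.auc
        assert drops >= 18


class TestRelativeRisk:
    def test_null_table(self):
        calls = [1, 1, 0, 0] * 10
        labels = [1, 0, 1, 0] * 10
        est = relative_risk(calls, labels)
        assert est.rr == pytest.approx(1.0)
        assert est.p_value == pytest.approx(1.0)

    def test_worked_table_rr_two(self):
        """a=20,b=20,c=10,d=30 -> RR 2.0, CI (1.076, 3.717), SE=sqrt(0.1)."""
        calls = np.repeat([1, 0], 40)
        labels = np.concatenate([np.repeat([1, 0], 20),
                                 np.repeat([1, 0], [10, 30])])
        est = relative_risk(calls, labels)
        assert (est.a, est.b, est.c, est.d) == (20, 20, 10, 30)
        assert est.rr == pytest.approx(2.0)
        assert est.ci_low == pytest.approx(1.076, abs=5e-4)
        assert est.ci_high == pytest.approx(3.717, abs=5e-4)

    def test_matches_statsmodels_on_random_tables(self, rng):
        """RR and CI agree with statsmodels' 2x2 table machinery on 100
        random all-positive-margin tables."""
        from statsmodels.stats.contingency_tables import Table2x2

        for _ in range(100):
            a, b, c, d = rng.integers(1, 50, size=4)
            calls = np.repeat([1, 1, 0, 0], [a, b, c, d])
            labels = np.repeat([1, 0, 1, 0], [a, b, c, d])
            est = relative_risk(calls, labels)
            t = Table2x2(np.array([[a, b], [c, d]]), shift_zeros=False)
            assert est.rr == pytest.approx(t.riskratio)
            lo, hi = t.riskratio_confint(0.05)
            assert est.ci_low == pytest.approx(lo, rel=1e-6)
            assert est.ci_high == pytest.approx(hi, rel=1e-6)

    def test_zero_cell_triggers_continuity_correction(self):
        calls = np.repeat([1, 1, 0, 0], [10, 0, 5, 10])
        labels = np.repeat([1, 0, 1, 0], [10, 0, 5, 10])
        est = relative_risk(calls, labels)
        assert est.continuity_corrected
        assert np.isfinite(est.rr) and est.rr > 1
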