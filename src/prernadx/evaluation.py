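"""Model evaluation and risk estimation.

AUC is the tie-corrected Mann-Whitney concordance (computed through the
standard ROC machinery); accuracy, sensitivity and specificity come from
a probability threshold, where the operating threshold of a final model
is derived from cross-validated out-of-fold scores by maximizing
Youden's J (sensitivity + specificity - 1), never from test data.
Repeated-split AUCs are summarized with a t-based 95% confidence
interval.  Frequently selected features across repeats are compiled into
compact final models, which are tested on a held-out 20% split plus an
independent leave-out set (samples never touched during model building),
and a positive/negative call at the frozen threshold yields a 2x2 table
from which the relative risk, its Wald log-scale confidence interval,
and a two-sided z p-value are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .ml import FitResult


class EvaluationError(ValueError):
    pass


@dataclass
class EvalResult:
    """ROC/threshold metrics on one scored sample set."""

    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: list[tuple[float, float]]  # (fpr, tpr)
    n_cases: int
    n_controls: int


@dataclass
class AggregateResult:
    """Mean AUC with a t-based 95% CI over repeated test sets."""

    mean_auc: float
    ci_low: float
    ci_high: float
    per_repeat: list[float]


@dataclass
class RiskEstimate:
    """Relative risk of a binary call against the case/control outcome."""

    threshold: float
    a: int  # test-positive cases
    b: int  # test-positive controls
    c: int  # test-negative cases
    d: int  # test-negative controls
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    continuity_corrected: bool = False


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> EvalResult:
    """AUC and ROC points; threshold metrics are filled at 0.5 by default.

    AUC equals the Mann-Whitney concordance probability with ties
    credited 1/2; the ROC curve sweeps thresholds downward with tied
    scores collapsed, so its trapezoidal area matches the AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise EvaluationError("scores must be finite")
    n_cases = int((labels == 1).sum())
    n_controls = int((labels == 0).sum())
    if n_cases == 0 or n_controls == 0:
        raise EvaluationError("need both classes to compute an ROC")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    acc, sn, sp = threshold_metrics(scores, labels, 0.5)
    return EvalResult(
        auc=auc,
        accuracy=acc,
        sensitivity=sn,
        specificity=sp,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        n_cases=n_cases,
        n_controls=n_controls,
    )


def evaluate_scores(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> EvalResult:
    """ROC/AUC plus threshold metrics at a given operating threshold."""
    res = roc_auc(scores, labels)
    res.accuracy, res.sensitivity, res.specificity = (
        threshold_metrics(scores, labels, threshold)
    )
    return res


def threshold_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with positive = score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise EvaluationError(
            "sensitivity/specificity undefined on single-class input"
        )
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    fp = int(np.sum(calls & (labels == 0)))
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    accuracy = (tp + tn) / len(labels)
    return accuracy, sensitivity, specificity


def optimal_cutpoint(
    cv_scores: Sequence[float],
    cv_labels: Sequence[int],
    metric: str = "youden",
) -> float:
    """Threshold maximizing Youden's J over out-of-fold CV scores.

    Candidates are midpoints between adjacent distinct scores; ties are
    broken toward the lowest threshold.  ``metric`` may also be
    'accuracy' or 'f1'.
    """
    scores = np.asarray(cv_scores, dtype=float)
    labels = np.asarray(cv_labels, dtype=int)
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise EvaluationError("all scores equal; no informative cutpoint")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best_thr, best_val = None, -np.inf
    for thr in candidates:  # ascending, so ties keep the lowest threshold
        calls = scores >= thr
        tp = np.sum(calls & (labels == 1))
        fn = np.sum(~calls & (labels == 1))
        tn = np.sum(~calls & (labels == 0))
        fp = np.sum(calls & (labels == 0))
        if metric == "youden":
            val = tp / (tp + fn) + tn / (tn + fp) - 1.0
        elif metric == "accuracy":
            val = (tp + tn) / len(labels)
        elif metric == "f1":
            val = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        else:
            raise EvaluationError(f"unknown cutpoint metric {metric!r}")
        if val > best_val + 1e-12:
            best_val, best_thr = val, float(thr)
    if metric == "youden" and best_val <= 0:
        warnings.warn(
            "cutpoint search found no threshold with positive Youden's J "
            "(anti-separated or uninformative scores)",
            UserWarning,
            stacklevel=2,
        )
    return best_thr


def aggregate_repeats(aucs: Sequence[float]) -> AggregateResult:
    """Mean AUC with a t-based 95% CI: mean +/- t_{n-1,0.975} * sd / sqrt(n)."""
    values = [float(v) for v in aucs]
    n = len(values)
    if n < 2:
        raise EvaluationError("need at least two repeats for a CI")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    half = float(stats.t.ppf(0.975, df=n - 1)) * sd / np.sqrt(n)
    return AggregateResult(
        mean_auc=mean, ci_low=mean - half, ci_high=mean + half, per_repeat=values
    )


@dataclass
class FeatureProfile:
    feature_id: str
    frequency: float  # fraction of repeats with nonzero importance
    mean_importance: float


def frequent_features(
    fit_results: Sequence[FitResult],
    top_n: int = 25,
    min_repeats: int = 3,
) -> list[FeatureProfile]:
    """Compile the features selected most often across repeated fits.

    Ranking is by selection frequency, then mean importance, then
    feature id; only features nonzero in at least ``min_repeats`` fits
    qualify.  The defaults match compact final panels of ~19-25 RNAs per
    histology.
    """
    n_rep = len(fit_results)
    if n_rep == 0:
        raise EvaluationError("no fit results supplied")
    count: dict[str, int] = {}
    imp_sum: dict[str, float] = {}
    for fit in fit_results:
        for fid, imp in fit.nonzero_features:
            count[fid] = count.get(fid, 0) + 1
            imp_sum[fid] = imp_sum.get(fid, 0.0) + imp
    eligible = [f for f, c in count.items() if c >= min_repeats]
    if not eligible:
        raise EvaluationError(
            f"no feature was selected in >= {min_repeats} of {n_rep} repeats"
        )
    profiles = [
        FeatureProfile(
            feature_id=f,
            frequency=count[f] / n_rep,
            mean_importance=imp_sum[f] / count[f],
        )
        for f in eligible
    ]
    profiles.sort(key=lambda p: (-p.frequency, -p.mean_importance, p.feature_id))
    return profiles[:top_n]


def leave_out_eval(
    test_scores: Sequence[float],
    test_labels: Sequence[int],
    leave_out_scores: Sequence[float],
    leave_out_labels: Sequence[int],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    leave_out_ids: Sequence[str],
    threshold: float = 0.5,
) -> tuple[EvalResult, EvalResult]:
    """Evaluate on the held-out test set alone and with the leave-out set.

    The leave-out set (non-smokers and smokers never used in frequency
    matching) must be disjoint from training; any overlap is a hard
    error naming the offending ids.
    """
    overlap = sorted(set(leave_out_ids) & set(train_ids))
    if overlap:
        raise EvaluationError(
            f"leave-out samples appear in training data: {overlap[:10]}"
        )
    overlap_test = sorted(set(leave_out_ids) & set(test_ids))
    if overlap_test:
        raise EvaluationError(
            f"leave-out samples duplicated in the test set: {overlap_test[:10]}"
        )
    test_only = evaluate_scores(test_scores, test_labels, threshold)
    combined = evaluate_scores(
        np.concatenate([np.asarray(test_scores, float),
                        np.asarray(leave_out_scores, float)]),
        np.concatenate([np.asarray(test_labels, int),
                        np.asarray(leave_out_labels, int)]),
        threshold,
    )
    return test_only, combined


def relative_risk(
    calls: Sequence[int], labels: Sequence[int], threshold: float = 0.5
) -> RiskEstimate:
    """Relative risk of being a case given a positive test call.

    rr = [a/(a+b)] / [c/(c+d)] on the 2x2 of call x outcome; the 95% CI
    is Wald on the log scale and the p-value a two-sided z-test on
    log rr.  Tables with a zero margin get a +0.5 continuity correction
    in every cell (flagged on the estimate).
    """
    calls = np.asarray(calls, dtype=int)
    labels = np.asarray(labels, dtype=int)
    a = int(np.sum((calls == 1) & (labels == 1)))
    b = int(np.sum((calls == 1) & (labels == 0)))
    c = int(np.sum((calls == 0) & (labels == 1)))
    d = int(np.sum((calls == 0) & (labels == 0)))
    if (a + b) == 0 and (c + d) == 0:
        raise EvaluationError("empty 2x2 table")
    corrected = False
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    if (aa + bb) == 0 or (cc + dd) == 0:
        raise EvaluationError("a test arm is empty even after correction")
    risk_pos = aa / (aa + bb)
    risk_neg = cc / (cc + dd)
    rr = risk_pos / risk_neg
    se = np.sqrt(1 / aa - 1 / (aa + bb) + 1 / cc - 1 / (cc + dd))
    log_rr = np.log(rr)
    ci_low = float(np.exp(log_rr - 1.959963984540054 * se))
    ci_high = float(np.exp(log_rr + 1.959963984540054 * se))
    z = log_rr / se if se > 0 else 0.0
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return RiskEstimate(
        threshold=threshold,
        a=a, b=b, c=c, d=d,
        rr=float(rr),
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        continuity_corrected=corrected,
    )
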