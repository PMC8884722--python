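"""Repeated matched train/test modeling with pluggable classifier backends.

The workflow mirrors a repeated holdout design: matched case-control
pairs are split 70/30 into train and test five times with designated
seeds, hyperparameters are tuned by grid search with stratified five-fold
cross-validation on the training split only, and the tuned model is
refit on the full training split and scored on the untouched test split.

Backends share one contract: ``predict_proba`` returns the case
probability and ``importances`` gives one non-negative number per
feature (|coefficient| for linear/sparse models, split gain for tree
ensembles).  Importances are therefore comparable within a backend but
not across backends; cross-model statements should use selection
frequency instead.

Three feature-selection strategies are provided: restriction to a single
RNA class, pooling of nonzero lasso coefficients across the repeated
splits followed by retraining, and univariate logistic screening with
Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests
from xgboost import XGBClassifier

from .cohort import Cohort, CohortError, RnaAnnotation
from .matching import Matching, WindowSpec, full_window, select_window
from .preprocess import NormalizedMatrix

MODEL_KINDS = (
    "lasso",
    "elastic_net",
    "sparse_group_lasso",
    "random_forest",
    "gradient_boosting",
)


class WorkflowError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """One seeded matched train/test partition of samples."""

    repeat_index: int
    seed: int
    train_ids: list[str]
    test_ids: list[str]
    unit: str  # individual | sample

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise WorkflowError("train and test sets overlap")


def make_splits(
    cohort: Cohort,
    matching: Matching,
    n_repeats: int = 5,
    train_frac: float = 0.7,
    base_seed: int = 0,
    unit: str = "individual",
) -> list[SplitPlan]:
    """Repeated matched train/test splits.

    Matched pairs move to train or test as whole units, preserving the
    1:1 case/control balance and the confounder matching on both sides.
    With ``unit='individual'``, pairs sharing any individual (e.g. two
    samples from one case donor matched to two controls) are merged into
    one unit so no individual ever spans the split.  The split of repeat
    ``r`` uses seed ``base_seed + r``.
    """
    if not 0.0 < train_frac < 1.0:
        raise WorkflowError("train_frac must be in (0, 1)")
    if unit not in ("individual", "sample"):
        raise WorkflowError(f"bad split unit {unit!r}")
    if len(matching.pairs) < 4:
        raise WorkflowError(
            f"only {len(matching.pairs)} matched pairs; too few to split"
        )

    indiv_of = {s.sample_id: s.individual_id for s in cohort.samples}
    if unit == "individual":
        # union-find over pairs sharing an individual
        parent = list(range(len(matching.pairs)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        by_indiv: dict[str, int] = {}
        for pi, (case_id, ctrl_id) in enumerate(matching.pairs):
            for sid in (case_id, ctrl_id):
                ind = indiv_of.get(sid, sid)
                if ind in by_indiv:
                    ra, rb = find(pi), find(by_indiv[ind])
                    if ra != rb:
                        parent[ra] = rb
                else:
                    by_indiv[ind] = pi
        groups: dict[int, list[int]] = {}
        for pi in range(len(matching.pairs)):
            groups.setdefault(find(pi), []).append(pi)
        units = sorted(groups.values(), key=lambda g: g[0])
    else:
        units = [[pi] for pi in range(len(matching.pairs))]

    unit_samples = [
        [sid for pi in u for sid in matching.pairs[pi]] for u in units
    ]
    total = sum(len(u) for u in unit_samples)
    target_train = train_frac * total

    plans: list[SplitPlan] = []
    for r in range(n_repeats):
        seed = base_seed + r
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(units))
        train: list[str] = []
        test: list[str] = []
        n_train = 0
        for ui in order:
            samp = unit_samples[ui]
            # add to train while that keeps us closer to the target
            if abs(n_train + len(samp) - target_train) <= abs(n_train - target_train):
                train.extend(samp)
                n_train += len(samp)
            else:
                test.extend(samp)
        if not train or not test:
            raise WorkflowError("split produced an empty side; too few pairs")
        plans.append(
            SplitPlan(
                repeat_index=r,
                seed=seed,
                train_ids=sorted(train),
                test_ids=sorted(test),
                unit=unit,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Backends
# ---------------------------------------------------------------------------


class FittedModel:
    """Uniform wrapper: case-probability scores + per-feature importances."""

    def __init__(
        self,
        predict: Callable[[np.ndarray], np.ndarray],
        importances: np.ndarray,
    ) -> None:
        self._predict = predict
        self.importances = np.asarray(importances, dtype=float)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._predict(np.asarray(X, dtype=float))


def default_grid(model_kind: str, n_features: int | None = None) -> list[dict]:
    """Default hyperparameter grids per backend."""
    if model_kind == "lasso":
        return [{"C": c} for c in np.logspace(-2, 2, 30)]
    if model_kind == "elastic_net":
        return [
            {"C": c, "l1_ratio": a}
            for a in (0.2, 0.5, 0.8)
            for c in np.logspace(-2, 2, 30)
        ]
    if model_kind == "sparse_group_lasso":
        return [{"lam": lam, "alpha": 0.5} for lam in np.logspace(-3, -0.5, 8)]
    if model_kind == "random_forest":
        grids = [{"n_estimators": 500, "max_features": "sqrt"}]
        if n_features:
            grids.append(
                {"n_estimators": 500, "max_features": max(1, n_features // 5)}
            )
        return grids
    if model_kind == "gradient_boosting":
        return [
            {"max_depth": d, "learning_rate": lr, "n_estimators": 200}
            for d in (2, 3, 4)
            for lr in (0.05, 0.1)
        ]
    raise WorkflowError(f"unknown model kind {model_kind!r}")


def fast_grid(model_kind: str) -> list[dict]:
    """Compact grids for desk-scale runs and the regression suite."""
    if model_kind == "lasso":
        return [{"C": c} for c in np.logspace(-1.5, 1, 6)]
    if model_kind == "elastic_net":
        return [{"C": c, "l1_ratio": 0.5} for c in np.logspace(-1.5, 1, 4)]
    if model_kind == "sparse_group_lasso":
        return [{"lam": lam, "alpha": 0.5} for lam in (0.03, 0.01)]
    if model_kind == "random_forest":
        return [{"n_estimators": 300, "max_features": "sqrt"}]
    if model_kind == "gradient_boosting":
        return [
            {"max_depth": d, "learning_rate": 0.1, "n_estimators": 100}
            for d in (2, 3)
        ]
    raise WorkflowError(f"unknown model kind {model_kind!r}")


def _fit_backend(
    model_kind: str,
    params: dict,
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    groups: np.ndarray | None = None,
) -> FittedModel:
    if not np.all(np.isfinite(X)):
        raise WorkflowError("non-finite values in feature matrix")
    if model_kind == "lasso":
        est = LogisticRegression(
            solver="liblinear", l1_ratio=1.0, C=params["C"], max_iter=2000,
            random_state=seed,
        )
        est.fit(X, y)
        return FittedModel(
            lambda Z: est.predict_proba(Z)[:, 1], np.abs(est.coef_[0])
        )
    if model_kind == "elastic_net":
        est = LogisticRegression(
            solver="saga",
            C=params["C"],
            l1_ratio=params.get("l1_ratio", 0.5),
            max_iter=3000,
            tol=1e-4,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X, y)
        return FittedModel(
            lambda Z: est.predict_proba(Z)[:, 1], np.abs(est.coef_[0])
        )
    if model_kind == "sparse_group_lasso":
        if groups is None:
            groups = np.zeros(X.shape[1], dtype=int)
        beta0, beta, mu, sd = _fit_sgl(
            X, y, groups,
            lam=params["lam"], alpha=params.get("alpha", 0.5),
        )

        def _pred(Z: np.ndarray) -> np.ndarray:
            Zs = (Z - mu) / sd
            return 1.0 / (1.0 + np.exp(-(beta0 + Zs @ beta)))

        return FittedModel(_pred, np.abs(beta))
    if model_kind == "random_forest":
        est = RandomForestClassifier(
            n_estimators=params.get("n_estimators", 500),
            max_features=params.get("max_features", "sqrt"),
            random_state=seed,
            n_jobs=1,
        )
        est.fit(X, y)
        return FittedModel(
            lambda Z: est.predict_proba(Z)[:, 1], est.feature_importances_
        )
    if model_kind == "gradient_boosting":
        est = XGBClassifier(
            max_depth=params.get("max_depth", 3),
            learning_rate=params.get("learning_rate", 0.1),
            n_estimators=params.get("n_estimators", 200),
            subsample=params.get("subsample", 1.0),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
        )
        est.fit(X, y)
        booster = est.get_booster()
        gain = booster.get_score(importance_type="gain")
        imp = np.zeros(X.shape[1])
        for name, g in gain.items():
            imp[int(name[1:])] = g  # feature names are f0, f1, ...
        return FittedModel(lambda Z: est.predict_proba(Z)[:, 1], imp)
    raise WorkflowError(f"unknown model kind {model_kind!r}")


def _fit_sgl(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    lam: float,
    alpha: float,
    max_iter: int = 5000,
    tol: float = 1e-6,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Sparse group lasso logistic regression by proximal gradient (ISTA).

    Minimizes mean logistic loss + lam * [alpha*||b||_1 +
    (1-alpha)*sum_g sqrt(p_g)*||b_g||_2] over standardized features with
    an unpenalized intercept.  Backtracking line search on the smooth
    part; stops when the objective improves by less than ``tol``.
    """
    n, p = X.shape
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    yy = np.asarray(y, dtype=float)

    group_ids = np.unique(groups)
    group_cols = [np.flatnonzero(groups == g) for g in group_ids]
    group_w = [np.sqrt(len(c)) for c in group_cols]

    beta = np.zeros(p)
    beta0 = 0.0

    def smooth_loss(b0: float, b: np.ndarray) -> tuple[float, float, np.ndarray]:
        eta = b0 + Xs @ b
        # stable log(1+exp)
        loss = np.mean(np.logaddexp(0.0, eta) - yy * eta)
        prob = 1.0 / (1.0 + np.exp(-eta))
        resid = prob - yy
        return loss, resid.mean(), Xs.T @ resid / n

    def penalty(b: np.ndarray) -> float:
        pen = alpha * np.abs(b).sum()
        for cols, w in zip(group_cols, group_w):
            pen += (1 - alpha) * w * np.linalg.norm(b[cols])
        return lam * pen

    def prox(b: np.ndarray, t: float) -> np.ndarray:
        # soft-threshold, then groupwise shrinkage
        out = np.sign(b) * np.maximum(np.abs(b) - t * lam * alpha, 0.0)
        for cols, w in zip(group_cols, group_w):
            norm = np.linalg.norm(out[cols])
            thr = t * lam * (1 - alpha) * w
            out[cols] = 0.0 if norm <= thr else out[cols] * (1 - thr / norm)
        return out

    step = 1.0
    loss, g0, grad = smooth_loss(beta0, beta)
    obj = loss + penalty(beta)
    for _ in range(max_iter):
        while True:
            cand = prox(beta - step * grad, step)
            cand0 = beta0 - step * g0
            new_loss, new_g0, new_grad = smooth_loss(cand0, cand)
            diff = cand - beta
            quad = loss + grad @ diff + (cand0 - beta0) * g0 \
                + (diff @ diff + (cand0 - beta0) ** 2) / (2 * step)
            if new_loss <= quad + 1e-12 or step < 1e-8:
                break
            step *= 0.5
        new_obj = new_loss + penalty(cand)
        improved = obj - new_obj
        beta, beta0 = cand, cand0
        loss, g0, grad = new_loss, new_g0, new_grad
        obj = new_obj
        if 0 <= improved < tol:
            break
        step = min(step * 1.5, 10.0)
    return beta0, beta, mu, sd


# ---------------------------------------------------------------------------
# Fit results and tuning
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """A tuned, trained classifier and its bookkeeping."""

    model_kind: str
    hyperparams: dict
    nonzero_features: list[tuple[str, float]]  # sorted by importance desc
    cv_auc: float
    model: FittedModel
    selection_strategy: str = "none"
    window: WindowSpec | None = None
    repeat_index: int = 0
    feature_ids: list[str] = field(default_factory=list)
    test_metrics: object | None = None  # EvalResult, attached by the workflow


def tune_and_fit(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    model_kind: str,
    grid: list[dict] | None = None,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> FitResult:
    """Grid search with stratified k-fold CV, then refit on all of train.

    The grid point with the highest mean CV AUC wins; ties go to the
    first point in grid order.  A single-point grid skips the CV pass
    and fits directly (cv_auc is then NaN).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise WorkflowError("training labels are single-class")
    if grid is None:
        grid = default_grid(model_kind, X.shape[1])
    if not grid:
        raise WorkflowError("empty hyperparameter grid")

    counts = np.bincount(y)
    can_cv = counts.min() >= k and k >= 2
    if len(grid) > 1 and not can_cv:
        raise WorkflowError(
            f"need at least {k} samples per class for {k}-fold CV"
        )

    best_params, best_auc = grid[0], float("nan")
    if len(grid) > 1 and can_cv:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        best_auc = -np.inf
        for params in grid:
            aucs = []
            for tr, va in folds:
                if len(np.unique(y[va])) < 2:
                    raise WorkflowError("single-class CV fold; check stratification")
                model = _fit_backend(model_kind, params, X[tr], y[tr], seed, groups)
                aucs.append(roc_auc_score(y[va], model.predict_proba(X[va])))
            mean_auc = float(np.mean(aucs))
            if mean_auc > best_auc + 1e-12:
                best_auc, best_params = mean_auc, params

    model = _fit_backend(model_kind, best_params, X, y, seed, groups)
    order = np.argsort(-model.importances, kind="stable")
    nonzero = [
        (feature_ids[i], float(model.importances[i]))
        for i in order
        if model.importances[i] > 0
    ]
    return FitResult(
        model_kind=model_kind,
        hyperparams=dict(best_params),
        nonzero_features=nonzero,
        cv_auc=float(best_auc),
        model=model,
        feature_ids=list(feature_ids),
    )


def cross_val_scores(
    X: np.ndarray,
    y: np.ndarray,
    model_kind: str,
    params: dict,
    k: int = 5,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Out-of-fold case-probability scores for every training sample."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    scores = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, va in skf.split(X, y):
        model = _fit_backend(model_kind, params, X[tr], y[tr], seed, groups)
        scores[va] = model.predict_proba(X[va])
    return scores


# ---------------------------------------------------------------------------
# Feature selection
# ---------------------------------------------------------------------------


def restrict_to_class(
    matrix: NormalizedMatrix,
    annotation: Sequence[RnaAnnotation],
    rna_class: str,
) -> NormalizedMatrix:
    """Keep only the features of one RNA class, order preserved."""
    class_of = {a.feature_id: a.rna_class for a in annotation}
    available = sorted({a.rna_class for a in annotation})
    if rna_class not in available:
        raise WorkflowError(
            f"RNA class {rna_class!r} absent; available: {available}"
        )
    keep = [
        j
        for j, f in enumerate(matrix.feature_ids)
        if class_of.get(f) == rna_class
    ]
    return NormalizedMatrix(
        values=matrix.values[:, keep],
        size_factors=matrix.size_factors,
        sample_ids=list(matrix.sample_ids),
        feature_ids=[matrix.feature_ids[j] for j in keep],
    )


@dataclass
class ScreenResult:
    feature_ids: list[str]  # significant features, original order
    p_values: np.ndarray
    q_values: np.ndarray
    flagged_separation: list[str]


def univariate_screen(
    X: np.ndarray,
    y: np.ndarray,
    feature_ids: Sequence[str],
    alpha: float = 0.05,
) -> ScreenResult:
    """Per-feature logistic regression with Benjamini-Hochberg control.

    Each feature gets a single-covariate logistic fit and a Wald p-value
    on its slope.  Constant features get p = 1 by convention.  Under
    complete separation the Wald statistic degenerates, so the p-value
    falls back to a likelihood-ratio test and the feature is flagged.
    Features with q <= alpha are retained.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if min(np.bincount(y)) < 2:
        raise WorkflowError("need at least two samples per class")
    n = len(y)
    p_values = np.ones(X.shape[1])
    flagged: list[str] = []
    ll_null = _bernoulli_loglik(np.full(n, y.mean()), y)
    for j in range(X.shape[1]):
        x = X[:, j]
        if np.ptp(x) == 0:
            continue
        p, separated = _logistic_wald_p(x, y, ll_null)
        p_values[j] = p
        if separated:
            flagged.append(feature_ids[j])
    reject, q_values, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    keep = [feature_ids[j] for j in range(X.shape[1]) if q_values[j] <= alpha]
    return ScreenResult(
        feature_ids=keep,
        p_values=p_values,
        q_values=q_values,
        flagged_separation=flagged,
    )


def _bernoulli_loglik(prob: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    prob = np.clip(prob, eps, 1 - eps)
    return float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))


def _logistic_wald_p(
    x: np.ndarray, y: np.ndarray, ll_null: float
) -> tuple[float, bool]:
    """Newton-fit single-covariate logistic regression; Wald or LRT p."""
    xs = (x - x.mean()) / (x.std() or 1.0)
    beta = np.zeros(2)  # intercept, slope
    X2 = np.column_stack([np.ones_like(xs), xs])
    separated = False
    for _ in range(50):
        eta = X2 @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        W = prob * (1 - prob)
        grad = X2.T @ (y - prob)
        H = (X2 * W[:, None]).T @ X2
        if np.linalg.cond(H) > 1e12 or W.max() < 1e-10:
            separated = True
            break
        delta = np.linalg.solve(H, grad)
        beta = beta + delta
        if np.abs(delta).max() < 1e-10:
            break
        if np.abs(beta[1]) > 30:
            separated = True
            break
    if not separated:
        eta = X2 @ beta
        prob = 1.0 / (1.0 + np.exp(-eta))
        W = prob * (1 - prob)
        H = (X2 * W[:, None]).T @ X2
        try:
            se = np.sqrt(np.linalg.inv(H)[1, 1])
        except np.linalg.LinAlgError:
            separated = True
        else:
            if not np.isfinite(se) or se == 0:
                separated = True
            else:
                z = beta[1] / se
                return 2.0 * float(stats.norm.sf(abs(z))), False
    # likelihood-ratio fallback (separation drives the fitted ll to ~0)
    eta = X2 @ beta
    prob = 1.0 / (1.0 + np.exp(-eta))
    ll_fit = _bernoulli_loglik(prob, y)
    lr = max(0.0, 2.0 * (ll_fit - ll_null))
    return float(stats.chi2.sf(lr, df=1)), True


def lasso_pool(
    split_plans: Sequence[SplitPlan],
    matrix: NormalizedMatrix,
    labels: dict[str, int],
    grid: list[dict] | None = None,
    k: int = 5,
) -> list[str]:
    """Union of nonzero lasso coefficients over the repeated training splits.

    Fits a tuned lasso on each repeat's training samples and pools the
    supports; downstream models restrict to this set before retraining.
    """
    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    pool: set[str] = set()
    for plan in split_plans:
        rows = [idx[s] for s in plan.train_ids]
        X = matrix.values[rows]
        y = np.array([labels[s] for s in plan.train_ids])
        fit = tune_and_fit(
            X, y, matrix.feature_ids, "lasso",
            grid=grid if grid is not None else fast_grid("lasso"),
            k=k, seed=plan.seed,
        )
        pool.update(f for f, _ in fit.nonzero_features)
    if not pool:
        raise WorkflowError(
            "lasso pooled no features; weaken the regularization grid"
        )
    return [f for f in matrix.feature_ids if f in pool]


# ---------------------------------------------------------------------------
# Workflow
# ---------------------------------------------------------------------------


def run_workflow(
    cohort: Cohort,
    matrix: NormalizedMatrix,
    matching: Matching,
    windows: Sequence[WindowSpec] | None = None,
    model_kinds: Sequence[str] = ("gradient_boosting",),
    strategies: Sequence[str] = ("none",),
    n_repeats: int = 5,
    train_frac: float = 0.7,
    base_seed: int = 0,
    unit: str = "individual",
    grids: dict[str, list[dict]] | None = None,
    k: int = 5,
    min_cases: int = 20,
    horizon: float = 10.0,
) -> list[FitResult]:
    """Run the full modeling grid: window x model x strategy x repeat.

    For each window the matched pairs whose case falls inside it are
    split ``n_repeats`` times; feature selection (where requested) is
    fit on the training split only, except lasso pooling, which by
    definition pools supports across the repeats' training splits before
    retraining.  Each fit is evaluated on its untouched test split.
    Windows capturing fewer than ``min_cases`` cases are skipped with a
    warning.  Strategies: 'none', 'lasso_pool', 'univariate', or
    'class:<rna_class>'.
    """
    from .evaluation import evaluate_scores  # late import to avoid a cycle

    if windows is None:
        windows = [full_window(horizon)]
    labels = {
        s.sample_id: 1 if s.group == "case" else 0 for s in cohort.samples
    }
    class_of = {a.feature_id: a.rna_class for a in cohort.annotation}
    col_of = {f: j for j, f in enumerate(matrix.feature_ids)}
    row_of = {s: i for i, s in enumerate(matrix.sample_ids)}
    results: list[FitResult] = []

    for window in windows:
        in_window = set(select_window(cohort, window, horizon=horizon))
        pairs = [
            (c, k_) for c, k_ in matching.pairs if c in in_window and k_ in in_window
        ]
        n_cases = len(pairs)
        if n_cases < min_cases:
            warnings.warn(
                f"window {window.label()}: only {n_cases} matched cases "
                f"(< {min_cases}); skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        sub_matching = Matching(pairs=pairs)
        plans = make_splits(
            cohort, sub_matching, n_repeats=n_repeats,
            train_frac=train_frac, base_seed=base_seed, unit=unit,
        )

        for strategy in strategies:
            if strategy.startswith("class:"):
                sub = restrict_to_class(
                    matrix, cohort.annotation, strategy.split(":", 1)[1]
                )
                strat_matrix, pooled = sub, None
            elif strategy == "lasso_pool":
                pooled = lasso_pool(
                    plans, matrix, labels,
                    grid=(grids or {}).get("lasso"), k=k,
                )
                cols = [col_of[f] for f in pooled]
                strat_matrix = NormalizedMatrix(
                    values=matrix.values[:, cols],
                    size_factors=matrix.size_factors,
                    sample_ids=list(matrix.sample_ids),
                    feature_ids=pooled,
                )
            else:
                strat_matrix, pooled = matrix, None

            for model_kind in model_kinds:
                grid = (grids or {}).get(model_kind)
                for plan in plans:
                    tr_rows = [row_of[s] for s in plan.train_ids]
                    te_rows = [row_of[s] for s in plan.test_ids]
                    Xtr = strat_matrix.values[tr_rows]
                    ytr = np.array([labels[s] for s in plan.train_ids])
                    fids = strat_matrix.feature_ids
                    if strategy == "univariate":
                        screen = univariate_screen(Xtr, ytr, fids)
                        if not screen.feature_ids:
                            warnings.warn(
                                f"univariate screen kept nothing for "
                                f"{window.label()} repeat {plan.repeat_index}",
                                UserWarning,
                                stacklevel=2,
                            )
                            continue
                        cols = [fids.index(f) for f in screen.feature_ids]
                        Xtr = Xtr[:, cols]
                        fids = screen.feature_ids
                    groups = None
                    if model_kind == "sparse_group_lasso":
                        classes = sorted({class_of.get(f, "?") for f in fids})
                        cls_idx = {c: i for i, c in enumerate(classes)}
                        groups = np.array(
                            [cls_idx[class_of.get(f, "?")] for f in fids]
                        )
                    fit = tune_and_fit(
                        Xtr, ytr, fids, model_kind,
                        grid=grid, k=k, seed=plan.seed, groups=groups,
                    )
                    fit.selection_strategy = strategy
                    fit.window = window
                    fit.repeat_index = plan.repeat_index
                    col_sel = [col_of[f] for f in fids]
                    Xte = matrix.values[np.ix_(te_rows, col_sel)]
                    yte = np.array([labels[s] for s in plan.test_ids])
                    scores = fit.model.predict_proba(Xte)
                    fit.test_metrics = evaluate_scores(scores, yte)
                    results.append(fit)
    return results
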