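"""End-to-end orchestration: simulate/load -> preprocess -> match ->
model -> evaluate -> (optional) enrich -> report.

A run is a pure function of its configuration (including the base seed):
re-running the same config writes byte-identical artifacts.  Every
defaulted parameter is echoed into ``run_log.json`` together with the
config hash, the split seeds, and any skipped-window warnings, so each
number in the report is traceable to a results file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from . import ml
from .cohort import (
    Cohort,
    CohortError,
    ConfounderEffects,
    SignalSpec,
    SimConfig,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .matching import (
    Matching,
    WindowSpec,
    enumerate_windows,
    fixed_windows,
    full_window,
    match_controls,
)
from .preprocess import filter_low_counts, size_factors, vst_normalize


class ConfigError(ValueError):
    pass


_ALLOWED_TOP = {
    "cohort_dir", "sim", "preprocess", "matching", "workflow",
    "frequent", "base_seed", "smokers_only",
}
_ALLOWED_SIM = {f.name for f in dataclasses.fields(SimConfig)}
_ALLOWED_PRE = {"min_reads", "min_fraction"}
_ALLOWED_MATCH = {"age_caliper"}
_ALLOWED_WF = {
    "windows", "histologies", "models", "strategies", "n_repeats",
    "train_frac", "unit", "min_cases", "grid", "horizon", "cv_folds",
}
_ALLOWED_FREQ = {"enabled", "top_n", "min_repeats", "model", "train_frac"}


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    sim: SimConfig | None = None
    cohort_dir: str | None = None
    min_reads: int = 5
    min_fraction: float = 0.8
    age_caliper: float = 5.0
    windows: str | list = "full"  # full | sliding | fixed | explicit list
    histologies: list[str] = field(default_factory=lambda: ["all"])
    models: list[str] = field(default_factory=lambda: ["gradient_boosting"])
    strategies: list[str] = field(default_factory=lambda: ["none"])
    n_repeats: int = 5
    train_frac: float = 0.7
    unit: str = "individual"
    min_cases: int = 20
    grid: str = "fast"  # fast | default
    horizon: float = 10.0
    cv_folds: int = 5
    smokers_only: bool = True
    frequent_enabled: bool = True
    frequent_top_n: int = 25
    frequent_min_repeats: int = 3
    frequent_model: str = "gradient_boosting"
    frequent_train_frac: float = 0.8
    base_seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _ALLOWED_TOP
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls()
        if "cohort_dir" in raw and "sim" in raw:
            raise ConfigError("give either cohort_dir or sim, not both")
        if "cohort_dir" in raw:
            cfg.cohort_dir = str(raw["cohort_dir"])
        else:
            sim_raw = dict(raw.get("sim", {}))
            unknown = set(sim_raw) - _ALLOWED_SIM
            if unknown:
                raise ConfigError(f"unknown sim keys: {sorted(unknown)}")
            if "confounder_effects" in sim_raw:
                sim_raw["confounder_effects"] = ConfounderEffects(
                    **sim_raw["confounder_effects"]
                )
            if "signal" in sim_raw:
                sim_raw["signal"] = [
                    SignalSpec(
                        feature_ids=tuple(s["feature_ids"]),
                        log2_fold_change=float(s["log2_fold_change"]),
                        histology=s.get("histology", "all"),
                        window=tuple(s["window"]) if s.get("window") else None,
                    )
                    for s in sim_raw["signal"]
                ]
            for key in ("nb_mean_log_range", "smoking_mix", "histology_mix",
                        "stage_mix", "bdg_labels", "bdg_mix_case",
                        "bdg_mix_control"):
                if key in sim_raw and sim_raw[key] is not None:
                    sim_raw[key] = tuple(sim_raw[key])
            cfg.sim = SimConfig(**sim_raw)
            cfg.sim.validate()
        pre = dict(raw.get("preprocess", {}))
        if set(pre) - _ALLOWED_PRE:
            raise ConfigError(f"unknown preprocess keys: {sorted(set(pre) - _ALLOWED_PRE)}")
        cfg.min_reads = int(pre.get("min_reads", cfg.min_reads))
        cfg.min_fraction = float(pre.get("min_fraction", cfg.min_fraction))
        mat = dict(raw.get("matching", {}))
        if set(mat) - _ALLOWED_MATCH:
            raise ConfigError(f"unknown matching keys: {sorted(set(mat) - _ALLOWED_MATCH)}")
        cfg.age_caliper = float(mat.get("age_caliper", cfg.age_caliper))
        wf = dict(raw.get("workflow", {}))
        if set(wf) - _ALLOWED_WF:
            raise ConfigError(f"unknown workflow keys: {sorted(set(wf) - _ALLOWED_WF)}")
        cfg.windows = wf.get("windows", cfg.windows)
        cfg.histologies = list(wf.get("histologies", cfg.histologies))
        cfg.models = list(wf.get("models", cfg.models))
        cfg.strategies = list(wf.get("strategies", cfg.strategies))
        cfg.n_repeats = int(wf.get("n_repeats", cfg.n_repeats))
        cfg.train_frac = float(wf.get("train_frac", cfg.train_frac))
        cfg.unit = str(wf.get("unit", cfg.unit))
        cfg.min_cases = int(wf.get("min_cases", cfg.min_cases))
        cfg.grid = str(wf.get("grid", cfg.grid))
        cfg.horizon = float(wf.get("horizon", cfg.horizon))
        cfg.cv_folds = int(wf.get("cv_folds", cfg.cv_folds))
        fr = dict(raw.get("frequent", {}))
        if set(fr) - _ALLOWED_FREQ:
            raise ConfigError(f"unknown frequent keys: {sorted(set(fr) - _ALLOWED_FREQ)}")
        cfg.frequent_enabled = bool(fr.get("enabled", cfg.frequent_enabled))
        cfg.frequent_top_n = int(fr.get("top_n", cfg.frequent_top_n))
        cfg.frequent_min_repeats = int(fr.get("min_repeats", cfg.frequent_min_repeats))
        cfg.frequent_model = str(fr.get("model", cfg.frequent_model))
        cfg.frequent_train_frac = float(fr.get("train_frac", cfg.frequent_train_frac))
        cfg.smokers_only = bool(raw.get("smokers_only", cfg.smokers_only))
        cfg.base_seed = int(raw.get("base_seed", cfg.base_seed))
        for model in cfg.models + [cfg.frequent_model]:
            if model not in ml.MODEL_KINDS:
                raise ConfigError(f"unknown model kind {model!r}")
        if cfg.grid not in ("fast", "default"):
            raise ConfigError("grid must be 'fast' or 'default'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.echo(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def resolve_windows(cfg: RunConfig) -> list[WindowSpec]:
    """Expand a windows preset (or explicit list) across histologies."""
    windows: list[WindowSpec] = []
    for hist in cfg.histologies:
        if cfg.windows == "full":
            windows.append(full_window(cfg.horizon, histology=hist))
        elif cfg.windows == "sliding":
            windows.extend(
                enumerate_windows([2, 3, 4], cfg.horizon, 1.0, histology=hist)
            )
        elif cfg.windows == "fixed":
            windows.extend(fixed_windows([2, 5, 8], histology=hist))
        elif cfg.windows == "standard":
            windows.append(full_window(cfg.horizon, histology=hist))
            windows.extend(
                enumerate_windows([2, 3, 4], cfg.horizon, 1.0, histology=hist)
            )
            windows.extend(fixed_windows([2, 5, 8], histology=hist))
        elif isinstance(cfg.windows, list):
            for w in cfg.windows:
                windows.append(
                    WindowSpec(
                        start=float(w["start"]), width=float(w["width"]),
                        kind=w.get("kind", "sliding"), histology=hist,
                    )
                )
        else:
            raise ConfigError(f"unknown windows preset {cfg.windows!r}")
    return windows


def run_all(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and write a report directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def log_event(stage: str, **kv: object) -> None:
        log.append({"stage": stage, **kv})

    # --- cohort -----------------------------------------------------------
    if config.cohort_dir is not None:
        base = Path(config.cohort_dir)
        cohort = read_cohort(
            base / "counts.tsv", base / "samples.tsv", base / "annotation.tsv"
        )
        log_event("load", cohort_dir=str(base), n_samples=cohort.n_samples)
    else:
        sim = config.sim if config.sim is not None else SimConfig(seed=config.base_seed)
        cohort = generate_cohort(sim)
        write_cohort(cohort, out / "cohort")
        log_event("simulate", seed=sim.seed, n_samples=cohort.n_samples,
                  n_features=cohort.n_features)

    # --- smoker restriction and leave-out partition -----------------------
    if config.smokers_only:
        smokers = [
            s.sample_id for s in cohort.samples
            if s.smoking in ("current", "former")
        ]
        non_smokers = [
            s.sample_id for s in cohort.samples
            if s.smoking not in ("current", "former")
        ]
    else:
        smokers = [s.sample_id for s in cohort.samples]
        non_smokers = []
    modeling = cohort.subset_samples(smokers)
    log_event("population", modeling=len(smokers), non_smokers=len(non_smokers))

    # --- preprocess -------------------------------------------------------
    filtered = filter_low_counts(
        modeling, min_reads=config.min_reads, min_fraction=config.min_fraction
    )
    kept = filtered.feature_ids
    # the same feature panel is applied to the whole cohort so leave-out
    # samples can be scored; factors are per-sample and leak nothing
    panel = cohort.subset_features(kept)
    factors = size_factors(panel.counts)
    matrix = vst_normalize(panel, factors)
    log_event("preprocess", kept_features=len(kept),
              min_reads=config.min_reads, min_fraction=config.min_fraction)

    # --- matching ---------------------------------------------------------
    cases = [s for s in modeling.samples if s.group == "case"]
    controls = [s for s in modeling.samples if s.group == "control"]
    matching = match_controls(cases, controls, age_caliper=config.age_caliper)
    log_event(
        "match", pairs=len(matching.pairs),
        unmatched_cases=len(matching.unmatched_cases),
        unused_controls=len(matching.unused_controls),
    )
    pd.DataFrame(matching.pairs, columns=["case_sample_id", "control_sample_id"]).to_csv(
        out / "matching.tsv", sep="\t", index=False
    )

    # --- workflow ---------------------------------------------------------
    windows = resolve_windows(config)
    grids = (
        {m: ml.fast_grid(m) for m in config.models}
        if config.grid == "fast" else None
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fits = ml.run_workflow(
            cohort=panel.subset_samples(smokers),
            matrix=_subset_matrix(matrix, smokers),
            matching=matching,
            windows=windows,
            model_kinds=config.models,
            strategies=config.strategies,
            n_repeats=config.n_repeats,
            train_frac=config.train_frac,
            base_seed=config.base_seed,
            unit=config.unit,
            grids=grids,
            k=config.cv_folds,
            min_cases=config.min_cases,
            horizon=config.horizon,
        )
    for w in caught:
        log_event("warning", message=str(w.message))
    log_event("workflow", n_fits=len(fits), base_seed=config.base_seed,
              grid=config.grid)

    _write_fit_tables(fits, out)

    # --- frequent features, leave-out test, relative risk -----------------
    if config.frequent_enabled and fits:
        risk_rows, freq_rows = _frequent_stage(
            config, cohort, matrix, matching, fits, non_smokers, log_event
        )
        if freq_rows:
            pd.DataFrame(freq_rows).to_csv(
                out / "frequent_features.tsv", sep="\t", index=False
            )
        if risk_rows:
            pd.DataFrame(risk_rows).to_csv(
                out / "risk.tsv", sep="\t", index=False
            )

    run_log = {
        "config": config.echo(),
        "config_hash": config.config_hash(),
        "events": log,
    }
    (out / "run_log.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True, default=str) + "\n"
    )
    (out / "report.txt").write_text(report(out))
    return out


def _subset_matrix(matrix, sample_ids):
    from .preprocess import NormalizedMatrix

    idx = {s: i for i, s in enumerate(matrix.sample_ids)}
    rows = [idx[s] for s in sample_ids]
    return NormalizedMatrix(
        values=matrix.values[rows],
        size_factors=matrix.size_factors[rows],
        sample_ids=list(sample_ids),
        feature_ids=list(matrix.feature_ids),
    )


def _write_fit_tables(fits: list[ml.FitResult], out: Path) -> None:
    rows = []
    for fit in fits:
        tm = fit.test_metrics
        rows.append({
            "window": fit.window.label() if fit.window else "full",
            "histology": fit.window.histology if fit.window else "all",
            "model": fit.model_kind,
            "strategy": fit.selection_strategy,
            "repeat": fit.repeat_index,
            "cv_auc": fit.cv_auc,
            "test_auc": tm.auc if tm else float("nan"),
            "accuracy": tm.accuracy if tm else float("nan"),
            "sensitivity": tm.sensitivity if tm else float("nan"),
            "specificity": tm.specificity if tm else float("nan"),
            "n_nonzero_features": len(fit.nonzero_features),
            "hyperparams": json.dumps(fit.hyperparams, sort_keys=True),
        })
    per_repeat = pd.DataFrame(rows)
    per_repeat.to_csv(out / "fits.tsv", sep="\t", index=False)

    if not per_repeat.empty:
        agg_rows = []
        keys = ["window", "histology", "model", "strategy"]
        for group_key, grp in per_repeat.groupby(keys, sort=True):
            entry = dict(zip(keys, group_key))
            if len(grp) >= 2:
                agg = ev.aggregate_repeats(grp["test_auc"].tolist())
                entry.update(
                    mean_auc=agg.mean_auc, ci_low=agg.ci_low, ci_high=agg.ci_high
                )
            else:
                entry.update(
                    mean_auc=float(grp["test_auc"].iloc[0]),
                    ci_low=float("nan"), ci_high=float("nan"),
                )
            entry["avg_nonzero_features"] = float(grp["n_nonzero_features"].mean())
            entry["avg_accuracy"] = float(grp["accuracy"].mean())
            entry["avg_sensitivity"] = float(grp["sensitivity"].mean())
            entry["avg_specificity"] = float(grp["specificity"].mean())
            entry["n_repeats"] = len(grp)
            agg_rows.append(entry)
        pd.DataFrame(agg_rows).to_csv(out / "metrics.tsv", sep="\t", index=False)
    # per-feature selection frequency / mean importance
    imp_rows: dict[tuple, dict] = {}
    for fit in fits:
        cfg_key = (
            fit.window.label() if fit.window else "full",
            fit.model_kind,
            fit.selection_strategy,
        )
        for fid, imp in fit.nonzero_features:
            row = imp_rows.setdefault(
                cfg_key + (fid,),
                {"window": cfg_key[0], "model": cfg_key[1],
                 "strategy": cfg_key[2], "feature_id": fid,
                 "times_selected": 0, "importance_sum": 0.0},
            )
            row["times_selected"] += 1
            row["importance_sum"] += imp
    if imp_rows:
        imp_df = pd.DataFrame(sorted(imp_rows.values(), key=lambda r: (
            r["window"], r["model"], r["strategy"], r["feature_id"])))
        imp_df["mean_importance"] = imp_df["importance_sum"] / imp_df["times_selected"]
        imp_df.drop(columns=["importance_sum"]).to_csv(
            out / "importances.tsv", sep="\t", index=False
        )


def _frequent_stage(config, cohort, matrix, matching, fits, non_smokers, log_event):
    """Compact final models per histology + leave-out testing + RR."""
    risk_rows, freq_rows = [], []
    labels = {s.sample_id: 1 if s.group == "case" else 0 for s in cohort.samples}
    col_of = {f: j for j, f in enumerate(matrix.feature_ids)}
    row_of = {s: i for i, s in enumerate(matrix.sample_ids)}
    full_fits_by_hist: dict[str, list[ml.FitResult]] = {}
    for fit in fits:
        if fit.window is not None and fit.window.kind == "full" \
                and fit.selection_strategy == "none":
            full_fits_by_hist.setdefault(fit.window.histology, []).append(fit)
    matched_ids = set(matching.case_ids) | set(matching.control_ids)
    leave_out_ids = sorted(
        set(non_smokers)
        | {s.sample_id for s in cohort.samples
           if s.sample_id not in matched_ids and s.sample_id not in non_smokers}
        - matched_ids
    )
    for hist, hist_fits in sorted(full_fits_by_hist.items()):
        try:
            profiles = ev.frequent_features(
                hist_fits, top_n=config.frequent_top_n,
                min_repeats=config.frequent_min_repeats,
            )
        except ev.EvaluationError as exc:
            log_event("frequent_skipped", histology=hist, reason=str(exc))
            continue
        feat_ids = [p.feature_id for p in profiles]
        for p in profiles:
            freq_rows.append({
                "histology": hist, "feature_id": p.feature_id,
                "frequency": p.frequency, "mean_importance": p.mean_importance,
            })
        # 80/20 matched split, single repeat, frozen CV threshold
        pairs = matching.pairs
        if hist != "all":
            hist_cases = {
                s.sample_id for s in cohort.samples if s.histology == hist
            }
            pairs = [(c, k) for c, k in matching.pairs if c in hist_cases]
        sub_matching = Matching(pairs=pairs)
        try:
            plan = ml.make_splits(
                cohort, sub_matching, n_repeats=1,
                train_frac=config.frequent_train_frac,
                base_seed=config.base_seed + 1000, unit=config.unit,
            )[0]
        except ml.WorkflowError as exc:
            log_event("frequent_skipped", histology=hist, reason=str(exc))
            continue
        cols = [col_of[f] for f in feat_ids]
        tr_rows = [row_of[s] for s in plan.train_ids]
        te_rows = [row_of[s] for s in plan.test_ids]
        Xtr = matrix.values[np.ix_(tr_rows, cols)]
        ytr = np.array([labels[s] for s in plan.train_ids])
        grid = (ml.fast_grid(config.frequent_model)
                if config.grid == "fast" else None)
        fit = ml.tune_and_fit(
            Xtr, ytr, feat_ids, config.frequent_model,
            grid=grid, k=config.cv_folds, seed=config.base_seed + 1000,
        )
        cv_scores = ml.cross_val_scores(
            Xtr, ytr, config.frequent_model, fit.hyperparams,
            k=config.cv_folds, seed=config.base_seed + 1000,
        )
        threshold = ev.optimal_cutpoint(cv_scores, ytr)
        Xte = matrix.values[np.ix_(te_rows, cols)]
        yte = np.array([labels[s] for s in plan.test_ids])
        te_scores = fit.model.predict_proba(Xte)
        lo_rows = [row_of[s] for s in leave_out_ids]
        Xlo = matrix.values[np.ix_(lo_rows, cols)]
        ylo = np.array([labels[s] for s in leave_out_ids])
        lo_scores = fit.model.predict_proba(Xlo) if leave_out_ids else np.array([])
        test_only, combined = ev.leave_out_eval(
            te_scores, yte, lo_scores, ylo,
            plan.train_ids, plan.test_ids, leave_out_ids,
            threshold=threshold,
        ) if leave_out_ids else (
            ev.evaluate_scores(te_scores, yte, threshold),
            ev.evaluate_scores(te_scores, yte, threshold),
        )
        rr_test = ev.relative_risk((te_scores >= threshold).astype(int), yte,
                                   threshold)
        all_scores = np.concatenate([te_scores, lo_scores])
        all_labels = np.concatenate([yte, ylo])
        rr_comb = ev.relative_risk(
            (all_scores >= threshold).astype(int), all_labels, threshold
        )
        for setting, eval_res, rr in (
            ("test_only", test_only, rr_test),
            ("test_plus_leave_out", combined, rr_comb),
        ):
            risk_rows.append({
                "histology": hist, "set": setting,
                "n_features": len(feat_ids), "threshold": threshold,
                "auc": eval_res.auc, "accuracy": eval_res.accuracy,
                "sensitivity": eval_res.sensitivity,
                "specificity": eval_res.specificity,
                "a": rr.a, "b": rr.b, "c": rr.c, "d": rr.d,
                "rr": rr.rr, "rr_ci_low": rr.ci_low, "rr_ci_high": rr.ci_high,
                "rr_p": rr.p_value,
            })
        log_event("frequent", histology=hist, n_features=len(feat_ids),
                  threshold=threshold, test_auc=test_only.auc,
                  combined_auc=combined.auc)
    return risk_rows, freq_rows


def report(results_dir: str | Path) -> str:
    """Human-readable summary of a results directory."""
    out = Path(results_dir)
    metrics_path = out / "metrics.tsv"
    if not metrics_path.exists():
        raise ConfigError(f"nothing to report: {metrics_path} is missing")
    lines = ["prernadx run report", "=" * 60, ""]
    metrics = pd.read_csv(metrics_path, sep="\t")
    lines.append("Model performance (mean test AUC with 95% CI over repeats):")
    for _, r in metrics.iterrows():
        ci = (
            f" ({r['ci_low']:.3f}-{r['ci_high']:.3f})"
            if np.isfinite(r.get("ci_low", float("nan"))) else ""
        )
        lines.append(
            f"  {r['window']:<22} {r['model']:<18} {r['strategy']:<12} "
            f"AUC {r['mean_auc']:.3f}{ci}  "
            f"av.#feat {r['avg_nonzero_features']:.1f}  "
            f"acc/sn/sp {100 * r['avg_accuracy']:.0f}/"
            f"{100 * r['avg_sensitivity']:.0f}/"
            f"{100 * r['avg_specificity']:.0f}"
        )
    risk_path = out / "risk.tsv"
    if risk_path.exists():
        risk = pd.read_csv(risk_path, sep="\t")
        lines += ["", "Frequent-feature models (relative risk at CV threshold):"]
        for _, r in risk.iterrows():
            lines.append(
                f"  {r['histology']:<6} {r['set']:<20} "
                f"{int(r['n_features'])} features  AUC {r['auc']:.3f}  "
                f"RR {r['rr']:.2f} ({r['rr_ci_low']:.2f}-{r['rr_ci_high']:.2f}) "
                f"p={r['rr_p']:.3g}"
            )
    lines.append("")
    return "\n".join(lines)
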