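"""Split plans, backend tuning, and the feature-selection strategies."""

import numpy as np
import pytest

from prernadx.cohort import Cohort, RnaAnnotation, SimConfig, generate_cohort
from prernadx.matching import Matching, match_controls
from prernadx.ml import (
    WorkflowError,
    fast_grid,
    lasso_pool,
    make_splits,
    restrict_to_class,
    run_workflow,
    tune_and_fit,
    univariate_screen,
)
from prernadx.preprocess import NormalizedMatrix, preprocess

from conftest import SMALL_FEATURES, make_case, make_control


def pair_cohort(n_pairs, extra_case_samples=()):
    """A toy cohort of matched pairs; some cases contribute two samples."""
    samples = []
    for i in range(n_pairs):
        ind = f"caseind{i}" if i not in extra_case_samples else f"caseind{i}"
        samples.append(make_case(f"c{i}", 50.0, 1.0, individual=f"caseind{i}"))
        samples.append(make_control(f"k{i}", 50.0, individual=f"ctrlind{i}"))
    for i in extra_case_samples:
        samples.append(
            make_case(f"c{i}x", 50.0, 2.0, individual=f"caseind{i}"))
        samples.append(make_control(f"k{i}x", 50.0,
                                    individual=f"ctrlind{i}x"))
    counts = np.ones((len(samples), 1), dtype=int)
    return Cohort(counts=counts, samples=samples,
                  annotation=[RnaAnnotation("miRNA_a", "miRNA")])


class TestMakeSplits:
    def test_ten_pairs_split_seven_three(self):
        cohort = pair_cohort(10)
        matching = Matching(pairs=[(f"c{i}", f"k{i}") for i in range(10)])
        plans = make_splits(cohort, matching, n_repeats=3, train_frac=0.7,
                            base_seed=5, unit="sample")
        for plan in plans:
            assert len(plan.train_ids) == 14 and len(plan.test_ids) == 6
            for side in (plan.train_ids, plan.test_ids):
                cases = [s for s in side if s.startswith("c")]
                ctrls = [s for s in side if s.startswith("k")]
                assert len(cases) == len(ctrls)

    def test_individual_unit_keeps_repeat_samples_together(self):
        cohort = pair_cohort(10, extra_case_samples=(0, 3))
        pairs = [(f"c{i}", f"k{i}") for i in range(10)]
        pairs += [("c0x", "k0x"), ("c3x", "k3x")]
        matching = Matching(pairs=pairs)
        plans = make_splits(cohort, matching, n_repeats=5, base_seed=2,
                            unit="individual")
        ind = {s.sample_id: s.individual_id for s in cohort.samples}
        for plan in plans:
            train_inds = {ind[s] for s in plan.train_ids}
            test_inds = {ind[s] for s in plan.test_ids}
            assert not train_inds & test_inds

    def test_same_seed_reproduces_plans(self):
        cohort = pair_cohort(8)
        matching = Matching(pairs=[(f"c{i}", f"k{i}") for i in range(8)])
        a = make_splits(cohort, matching, base_seed=9)
        b = make_splits(cohort, matching, base_seed=9)
        assert [(p.train_ids, p.test_ids) for p in a] == \
               [(p.train_ids, p.test_ids) for p in b]

    def test_repeats_differ(self):
        cohort = pair_cohort(12)
        matching = Matching(pairs=[(f"c{i}", f"k{i}") for i in range(12)])
        plans = make_splits(cohort, matching, n_repeats=5, base_seed=0)
        assert len({tuple(p.train_ids) for p in plans}) > 1

    def test_too_few_pairs_errors(self):
        cohort = pair_cohort(2)
        matching = Matching(pairs=[("c0", "k0"), ("c1", "k1")])
        with pytest.raises(WorkflowError):
            make_splits(cohort, matching)


def separable_data(n=60, p=20, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = np.repeat([0, 1], n // 2)
    X[:, 7] = y * 4.0 + rng.normal(scale=0.1, size=n)
    return X, y, [f"f{j}" for j in range(p)]


class TestTuneAndFit:
    def test_perfect_separator_found(self):
        X, y, fids = separable_data()
        fit = tune_and_fit(X, y, fids, "lasso", grid=fast_grid("lasso"),
                           seed=1)
        assert fit.cv_auc == pytest.approx(1.0)
        assert fit.nonzero_features[0][0] == "f7"

    def test_single_point_grid_matches_direct_fit(self):
        X, y, fids = separable_data(seed=3)
        fit1 = tune_and_fit(X, y, fids, "lasso", grid=[{"C": 0.5}], seed=1)
        fit2 = tune_and_fit(X, y, fids, "lasso", grid=[{"C": 0.5}], seed=1)
        assert fit1.hyperparams == {"C": 0.5}
        assert fit1.nonzero_features == fit2.nonzero_features
        assert np.isnan(fit1.cv_auc)

    def test_permutation_null_cv_auc_near_half(self):
        """Random labels give CV AUC ~0.5 on average over permutations."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(80, 15))
        fids = [f"f{j}" for j in range(15)]
        aucs = []
        for rep in range(20):
            y = rng.permutation(np.repeat([0, 1], 40))
            fit = tune_and_fit(X, y, fids, "lasso", grid=[{"C": 1.0}, {"C": 0.1}],
                               seed=rep)
            aucs.append(fit.cv_auc)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.02

    def test_single_class_labels_error(self):
        X = np.zeros((10, 3))
        with pytest.raises(WorkflowError):
            tune_and_fit(X, np.zeros(10, dtype=int), ["a", "b", "c"], "lasso")

    @pytest.mark.parametrize("model_kind", ["lasso", "elastic_net",
                                            "sparse_group_lasso",
                                            "random_forest",
                                            "gradient_boosting"])
    def test_every_backend_learns_a_strong_signal(self, model_kind):
        X, y, fids = separable_data(n=80, seed=6)
        groups = np.array([j % 3 for j in range(X.shape[1])])
        fit = tune_and_fit(X, y, fids, model_kind,
                           grid=fast_grid(model_kind), seed=2, groups=groups)
        if not np.isnan(fit.cv_auc):  # single-point grids skip the CV pass
            assert fit.cv_auc > 0.9
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(y, fit.model.predict_proba(X)) > 0.95
        assert all(imp >= 0 for _, imp in fit.nonzero_features)
        imps = [imp for _, imp in fit.nonzero_features]
        assert imps == sorted(imps, reverse=True)

    def test_sgl_group_sparsity(self):
        """At strong regularization whole uninformative groups are zeroed."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 12))
        y = (X[:, 0] + X[:, 1] + rng.normal(scale=0.5, size=100) > 0).astype(int)
        groups = np.repeat([0, 1, 2], 4)
        fit = tune_and_fit(X, y, [f"f{j}" for j in range(12)],
                           "sparse_group_lasso",
                           grid=[{"lam": 0.08, "alpha": 0.5}], seed=0,
                           groups=groups)
        support = {f for f, _ in fit.nonzero_features}
        assert {"f0", "f1"} & support
        # the two noise groups should be fully or almost fully zeroed
        noise_selected = [f for f in support if int(f[1:]) >= 4]
        assert len(noise_selected) <= 2


class TestRestrictToClass:
    def make_matrix(self):
        ann = [RnaAnnotation("m1", "miRNA"), RnaAnnotation("m2", "miRNA"),
               RnaAnnotation("m3", "miRNA"), RnaAnnotation("t1", "tRF"),
               RnaAnnotation("t2", "tRF")]
        matrix = NormalizedMatrix(
            values=np.arange(10.0).reshape(2, 5),
            size_factors=np.ones(2),
            sample_ids=["s1", "s2"],
            feature_ids=[a.feature_id for a in ann],
        )
        return matrix, ann

    def test_counts_and_order(self):
        matrix, ann = self.make_matrix()
        sub = restrict_to_class(matrix, ann, "tRF")
        assert sub.feature_ids == ["t1", "t2"]
        assert np.array_equal(sub.values, matrix.values[:, 3:])

    def test_identity_when_class_covers_all(self):
        matrix, ann = self.make_matrix()
        only_mirna = restrict_to_class(matrix, ann, "miRNA")
        again = restrict_to_class(only_mirna, ann, "miRNA")
        assert again.feature_ids == only_mirna.feature_ids

    def test_absent_class_lists_available(self):
        matrix, ann = self.make_matrix()
        with pytest.raises(WorkflowError, match="miRNA"):
            restrict_to_class(matrix, ann, "piRNA")


class TestUnivariateScreen:
    def test_bh_thresholds(self):
        """Constructed features whose Wald p-values BH-survive as expected.

        With m=4 p-values (0.001, 0.02, 0.03, 0.2), BH at alpha=0.05 keeps
        the first three; verified here against statsmodels' fdr_bh on the
        same vector, and structurally via a constant (p=1) feature.
        """
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.02, 0.03, 0.2])
        reject, q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert reject.tolist() == [True, True, True, False]
        assert q == pytest.approx([0.004, 0.04, 0.04, 0.2])

    def test_constant_feature_gets_p_one_and_is_dropped(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = np.repeat([0, 1], 20)
        X[:, 1] += y * 3.0
        res = univariate_screen(X, y, ["const", "signal"])
        assert res.p_values[0] == 1.0
        assert res.feature_ids == ["signal"]

    def test_separated_feature_flagged_but_significant(self):
        X = np.column_stack([np.repeat([0.0, 10.0], 25)])
        y = np.repeat([0, 1], 25)
        res = univariate_screen(X, y, ["sep"])
        assert res.feature_ids == ["sep"]
        assert res.flagged_separation == ["sep"]

    def test_planted_feature_power(self):
        """A planted LFC>=1.5 feature at n=200 is retained with q<0.05.

        Checked over 40 simulation runs; the retention rate must be at
        least 95%.
        """
        rng = np.random.default_rng(12)
        hits = 0
        runs = 40
        for _ in range(runs):
            n = 200
            y = np.repeat([0, 1], n // 2)
            X = rng.normal(size=(n, 10))
            X[:, 4] += y * 1.0  # ~1 sd shift, comparable to LFC 1.5 counts
            res = univariate_screen(X, y, [f"f{j}" for j in range(10)])
            hits += "f4" in res.feature_ids
        assert hits / runs >= 0.95


class TestLassoPool:
    def test_union_of_supports(self):
        cohort = pair_cohort(20)
        rng = np.random.default_rng(3)
        values = rng.normal(size=(cohort.n_samples, 12))
        y = {s.sample_id: int(s.group == "case") for s in cohort.samples}
        yy = np.array([y[s] for s in cohort.sample_ids])
        values[:, 2] += yy * 3.0
        matrix = NormalizedMatrix(
            values=values, size_factors=np.ones(cohort.n_samples),
            sample_ids=cohort.sample_ids,
            feature_ids=[f"f{j}" for j in range(12)],
        )
        matching = Matching(pairs=[(f"c{i}", f"k{i}") for i in range(20)])
        plans = make_splits(cohort, matching, n_repeats=3, base_seed=1,
                            unit="sample")
        pooled = lasso_pool(plans, matrix, y)
        assert "f2" in pooled
        single = lasso_pool(plans[:1], matrix, y)
        assert set(single) <= set(pooled)


class TestRunWorkflow:
    @pytest.fixture(scope="module")
    def prepared(self):
        cfg = SimConfig(n_case_individuals=40, n_control_individuals=60,
                        features_per_class=dict(SMALL_FEATURES), seed=21)
        cohort = generate_cohort(cfg)
        filtered, matrix = preprocess(cohort)
        cases = [s for s in cohort.samples if s.group == "case"]
        controls = [s for s in cohort.samples if s.group == "control"]
        matching = match_controls(cases, controls)
        return filtered, matrix, matching

    def test_one_config_yields_one_fit_per_repeat(self, prepared):
        filtered, matrix, matching = prepared
        fits = run_workflow(filtered, matrix, matching,
                            model_kinds=["lasso"], strategies=["none"],
                            n_repeats=5, base_seed=7,
                            grids={"lasso": fast_grid("lasso")},
                            min_cases=5)
        assert len(fits) == 5
        assert sorted(f.repeat_index for f in fits) == [0, 1, 2, 3, 4]
        for f in fits:
            assert f.test_metrics is not None
            assert 0.0 <= f.test_metrics.auc <= 1.0

    def test_no_leakage_across_any_fit(self, prepared):
        filtered, matrix, matching = prepared
        plans = make_splits(filtered, matching, n_repeats=5, base_seed=7)
        ind = {s.sample_id: s.individual_id for s in filtered.samples}
        for p in plans:
            assert not set(p.train_ids) & set(p.test_ids)
            assert not {ind[s] for s in p.train_ids} & \
                   {ind[s] for s in p.test_ids}

    def test_tiny_window_skipped_with_warning(self, prepared):
        from prernadx.matching import WindowSpec

        filtered, matrix, matching = prepared
        with pytest.warns(UserWarning, match="skipped"):
            fits = run_workflow(
                filtered, matrix, matching,
                windows=[WindowSpec(9, 1)],
                model_kinds=["lasso"], strategies=["none"],
                grids={"lasso": fast_grid("lasso")}, min_cases=20,
            )
        assert fits == []

    def test_workflow_deterministic(self, prepared):
        filtered, matrix, matching = prepared
        kw = dict(model_kinds=["lasso"], strategies=["none"], n_repeats=2,
                  base_seed=3, grids={"lasso": fast_grid("lasso")},
                  min_cases=5)
        a = run_workflow(filtered, matrix, matching, **kw)
        b = run_workflow(filtered, matrix, matching, **kw)
        assert [f.nonzero_features for f in a] == \
               [f.nonzero_features for f in b]
        assert [f.test_metrics.auc for f in a] == \
               [f.test_metrics.auc for f in b]
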