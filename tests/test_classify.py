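import itertools

import numpy as np
import pandas as pd
import pytest

import carcinogenome as cg
from carcinogenome import classify as cl
from carcinogenome.core import ValidationError


def auc_by_pair_counting(scores, labels):
    """Concordant-pair oracle: ties count one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    pos = scores[y]
    neg = scores[~y]
    total = 0.0
    for sp, sn in itertools.product(pos, neg):
        total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


class TestComputeAUC:
    def test_separated_scores(self):
        assert cl.compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_interleaved_scores(self):
        # 2 of 4 pairs concordant
        assert cl.compute_auc([0.9, 0.1, 0.8, 0.2], [1, 1, 0, 0]) == 0.5

    def test_all_ties(self):
        assert cl.compute_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        assert cl.compute_auc(scores, labels) == pytest.approx(
            auc_by_pair_counting(scores, labels), abs=1e-12
        )

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            cl.compute_auc([0.2, 0.8], [1, 1])


class TestSplitPlans:
    def test_seventy_thirty_stratified(self):
        compounds = [f"c{i}" for i in range(10)]
        labels = pd.Series([True] * 5 + [False] * 5, index=compounds)
        plans = cl.make_split_plans(compounds, labels, n_iter=200, seed=1)
        for plan in plans:
            assert len(plan.train_compounds) == 7 and len(plan.test_compounds) == 3
            assert not set(plan.train_compounds) & set(plan.test_compounds)
            test_pos = sum(labels[c] for c in plan.test_compounds)
            assert 1 <= test_pos <= 2  # >=1 compound of each class in test

    def test_deterministic_under_seed(self):
        compounds = [f"c{i}" for i in range(12)]
        labels = pd.Series([True] * 4 + [False] * 8, index=compounds)
        a = cl.make_split_plans(compounds, labels, n_iter=20, seed=9)
        b = cl.make_split_plans(compounds, labels, n_iter=20, seed=9)
        assert [(p.train_compounds, p.test_compounds) for p in a] == [
            (p.train_compounds, p.test_compounds) for p in b
        ]

    def test_single_compound_class_rejected(self):
        compounds = ["a", "b", "c"]
        labels = pd.Series([True, False, False], index=compounds)
        with pytest.raises(ValidationError):
            cl.make_split_plans(compounds, labels)


class TestFeatureSelection:
    def test_variance_filter_picks_highest(self):
        X = pd.DataFrame({"f0": [1.0, 1.0, 1.0], "f1": [0.0, 1.0, 2.0], "f2": [0.0, 2.0, 4.0]})
        assert cl.variance_filter(X, 1) == ["f2"]
        assert cl.variance_filter(X, 3) == ["f2", "f1", "f0"]

    def test_variance_filter_overflow_uses_all(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)), columns=list("abc"))
        assert sorted(cl.variance_filter(X, 10)) == ["a", "b", "c"]

    def test_rank_filter_by_t_blocks(self):
        rng = np.random.default_rng(1)
        y = pd.Series([True] * 10 + [False] * 10)
        X = pd.DataFrame(rng.normal(size=(20, 6)), columns=[f"f{i}" for i in range(6)])
        X.loc[y.to_numpy(), "f3"] += 5.0  # strongest signal
        top = cl.rank_filter_by_t(X, y, n=1)
        assert top == ["f3"]
        second_block = cl.rank_filter_by_t(X, y, n=1, block=1)
        assert second_block != ["f3"]

    def test_selection_ignores_test_data(self):
        # selection computed on the training rows is unchanged by any
        # perturbation of held-out rows
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(30, 8)), columns=[f"f{i}" for i in range(8)])
        train = X.iloc[:20]
        chosen = cl.variance_filter(train, 4)
        X_tainted = X.copy()
        X_tainted.iloc[20:] = 1e6
        assert cl.variance_filter(X_tainted.iloc[:20], 4) == chosen


class TestThresholdMetrics:
    def test_perfect_separation_zero_one_loss(self):
        m = cl.threshold_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0],
                                 [0.95, 0.05], [1, 0])
        assert m["sensitivity"] == 1.0 and m["specificity"] == 1.0

    def test_manual_six_sample_confusion(self):
        # train picks threshold 0.5; test has TP=2 FP=1 FN=1 TN=2
        train_s, train_y = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1], [1, 1, 1, 0, 0, 0]
        test_s = [0.9, 0.6, 0.4, 0.7, 0.2, 0.3]
        test_y = [1, 1, 1, 0, 0, 0]
        m = cl.threshold_metrics(train_s, train_y, test_s, test_y)
        assert (m["tp"], m["fp"], m["fn"], m["tn"]) == (2, 1, 1, 2)
        assert m["accuracy"] == pytest.approx(4 / 6)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["ppv"] == pytest.approx(2 / 3)
        assert m["fdr"] == pytest.approx(1 / 3)

    def test_fn_cost_increase_never_lowers_training_sensitivity(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(size=40)
        y = (s + rng.normal(scale=0.3, size=40)) > 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        prev_sens = -1.0
        for fn_cost in (1.0, 2.0, 5.0, 10.0):
            thr = cl.choose_threshold(s, y, cl.CostSpec(1.0, fn_cost))
            sens = np.sum((s > thr) & y) / y.sum()
            assert sens >= prev_sens - 1e-12
            prev_sens = sens

    def test_cost_tie_picks_lowest_threshold(self):
        # inverted labels: call-all-positive and call-all-negative tie at
        # cost 1; the lowest candidate threshold must win
        thr = cl.choose_threshold([0.2, 0.8], [1, 0], cl.CostSpec(1.0, 1.0))
        assert thr < 0.2


class TestConfidenceFilter:
    def test_middle_band_dropped(self):
        p = pd.Series([0.9, 0.5, 0.1], index=["a", "b", "c"])
        out = cl.confidence_filter(p)
        assert list(out.index) == ["a", "c"]
        assert out.loc["a", "call"] and not out.loc["c", "call"]

    def test_equal_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            cl.confidence_filter(pd.Series([0.5]), hi=0.5, lo=0.5)

    def test_retained_count_matches_manual(self):
        rng = np.random.default_rng(4)
        p = pd.Series(rng.uniform(size=200))
        out = cl.confidence_filter(p, hi=0.7, lo=0.2)
        assert len(out) == int(((p > 0.7) | (p < 0.2)).sum())


class TestRandomForest:
    def test_separable_toy_training_auc_one(self):
        X = pd.DataFrame({"f0": [0, 0, 0, 1, 1, 1], "f1": [1, 1, 1, 0, 0, 0]}, dtype=float)
        y = pd.Series([False] * 3 + [True] * 3)
        model = cl.train_rf(X, y, n_trees=50, seed=0)
        s = model.score_samples(X.to_numpy())
        assert cl.compute_auc(s, y) == 1.0

    def test_label_permuted_training_no_signal(self):
        rng = np.random.default_rng(5)
        aucs = []
        for seed in range(50):
            X = rng.normal(size=(40, 10))
            y = np.array([True] * 20 + [False] * 20)
            rng.shuffle(y)
            model = cl.RandomForestModel(n_trees=50, seed=seed).fit(X[:30], y[:30])
            if len(set(y[30:])) < 2:
                continue
            aucs.append(cl.compute_auc(model.score_samples(X[30:]), y[30:]))
        mean = np.mean(aucs)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(mean - 0.5) < 4 * se + 0.02

    def test_perfect_feature_ranks_first_in_importance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 8))
        y = rng.integers(0, 2, size=60).astype(bool)
        X[:, 3] = y.astype(float)  # injected perfectly predictive feature
        model = cl.RandomForestModel(n_trees=100, seed=1).fit(X, y)
        imp = model.permutation_importance(X, y)
        assert np.argmax(imp) == 3

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValidationError):
            cl.RandomForestModel(n_trees=10, seed=0).fit(np.ones((4, 2)), np.ones(4))


class TestRunResampling:
    def test_deterministic_under_master_seed(self, single_module_cohort):
        ds, ann, _ = single_module_cohort
        a = cl.run_resampling(ds, ds.meta, ann, n_iter=4, n_features=100, n_trees=100, seed=3)
        b = cl.run_resampling(ds, ds.meta, ann, n_iter=4, n_features=100, n_trees=100, seed=3)
        np.testing.assert_array_equal(a.auc_per_iteration, b.auc_per_iteration)
        pd.testing.assert_frame_equal(a.metrics, b.metrics)

    def test_strong_cohort_high_auc(self, single_module_cohort):
        ds, ann, _ = single_module_cohort
        res = cl.run_resampling(ds, ds.meta, ann, n_iter=6, n_features=100, n_trees=200, seed=4)
        assert res.mean_auc > 0.9
        assert res.ci95[0] <= res.mean_auc <= res.ci95[1]

    def test_no_compound_straddles_split(self, single_module_cohort):
        ds, ann, _ = single_module_cohort
        res = cl.run_resampling(ds, ds.meta, ann, n_iter=4, n_features=50, n_trees=50, seed=5)
        preds = res.predictions
        cpd_of = ds.meta["compound"]
        for it, sub in preds.groupby("iteration"):
            test_cpds = set(cpd_of[sub["sample_id"]])
            # every replicate of a test compound is in the test predictions
            for cpd in test_cpds:
                reps = set(ds.meta.index[(cpd_of == cpd)])
                assert reps <= set(sub["sample_id"])

    def test_feature_selection_sees_only_training_samples(self, single_module_cohort, monkeypatch):
        ds, ann, _ = single_module_cohort
        seen = []
        orig = cl.variance_filter

        def recorder(train, n=500):
            seen.append(set(train.index))
            return orig(train, n)

        monkeypatch.setattr(cl, "variance_filter", recorder)
        res = cl.run_resampling(ds, ds.meta, ann, n_iter=3, n_features=50, n_trees=50, seed=6)
        preds = res.predictions
        for it_seen, (it, sub) in zip(seen, preds.groupby("iteration")):
            assert not it_seen & set(sub["sample_id"])

    def test_compound_split_less_optimistic_than_sample_split(self):
        # replicate-correlated null: each compound has its own random offset,
        # labels are random at the compound level; sample-level splitting
        # leaks compound identity and inflates AUC
        rng = np.random.default_rng(7)
        compounds = [f"c{i}" for i in range(16)]
        labels = pd.Series(rng.permutation([True] * 8 + [False] * 8), index=compounds)
        rows, meta_rows = [], []
        offsets = {c: rng.normal(size=10) * 2.0 for c in compounds}
        for c in compounds:
            for r in range(4):
                rows.append(offsets[c] + rng.normal(size=10) * 0.2)
                meta_rows.append({"sample_id": f"{c}_r{r}", "compound": c, "dose_level": "high"})
        X = pd.DataFrame(rows, index=[m["sample_id"] for m in meta_rows])
        meta = pd.DataFrame(meta_rows).set_index("sample_id")
        ann = cg.CompoundAnnotation(pd.DataFrame({
            "carcinogenic": ["positive" if labels[c] else "negative" for c in compounds],
            "genotoxic": "unknown",
        }, index=pd.Index(compounds, name="compound")))
        res_cpd = cl.run_resampling(X, meta, ann, n_iter=15, selector="none",
                                    n_features=10, n_trees=100, seed=8)
        # sample-level splitting: pretend each sample is its own compound
        meta_leaky = meta.copy()
        meta_leaky["compound"] = meta_leaky.index
        ann_leaky = cg.CompoundAnnotation(pd.DataFrame({
            "carcinogenic": ["positive" if labels[meta.loc[s, "compound"]] else "negative"
                             for s in meta_leaky.index],
            "genotoxic": "unknown",
        }, index=pd.Index(meta_leaky.index, name="compound")))
        res_sample = cl.run_resampling(X, meta_leaky, ann_leaky, n_iter=15, selector="none",
                                       n_features=10, n_trees=100, seed=8)
        assert res_sample.mean_auc >= res_cpd.mean_auc
        assert res_sample.mean_auc > 0.8  # leakage memorizes compounds
        assert abs(res_cpd.mean_auc - 0.5) < 0.18  # honest evaluation stays null


class TestExternalValidation:
    def test_shared_compounds_excluded(self, single_module_cohort):
        ds, ann, _ = single_module_cohort
        # pretend half the compounds of the validation cohort are new by
        # renaming them; the other half overlap the discovery cohort
        rename = {c: f"x_{c}" for i, c in enumerate(ann.compounds) if i % 2}
        test_meta = ds.meta.copy()
        test_meta["compound"] = test_meta["compound"].map(lambda c: rename.get(c, c))
        tab = ann.table.rename(index=rename)
        ann_test = cg.CompoundAnnotation(tab)
        out = cl.external_validation(ds, ds, ds.meta, test_meta, ann, ann_test,
                                     exclude_shared_compounds=True, n_features=50, n_trees=50)
        kept_cpds = set(test_meta.loc[out["sample_scores"].index, "compound"])
        assert kept_cpds == set(rename.values())
        # with exclusion off, every treated sample is scored
        out2 = cl.external_validation(ds, ds, ds.meta, test_meta, ann, ann_test,
                                      exclude_shared_compounds=False, n_features=50, n_trees=50)
        assert len(out2["sample_scores"]) == len(ds.treated_ids())


class TestLearningCurve:
    def test_series_length_and_reject(self, single_module_cohort):
        ds, ann, _ = single_module_cohort
        lc = cl.learning_curve(ds, ds.meta, ann, start=12, step=6, n_iter=3,
                               n_features=50, n_trees=50, seed=1)
        total = len(ann.table)
        assert len(lc["table"]) == (total - 12) // 6 + 1
        with pytest.raises(ValidationError):
            cl.learning_curve(ds, ds.meta, ann, start=10_000)


class TestStratifiedGrid:
    def test_single_class_stratum_flagged(self):
        spec = cg.CohortSpec(n_genes=100, n_compounds=6, frac_carcinogenic=0.2,
                             n_moa_modules=1, module_size=10, dose_levels=("high",),
                             dose_response=(1.0,), times=(29.0,), seed=13)
        ds, ann, _ = cg.generate_cohort(spec)
        # force one class: flip all labels positive
        tab = ann.table.copy()
        tab["carcinogenic"] = "positive"
        grid = cl.stratified_auc_grid(ds, ds.meta, cg.CompoundAnnotation(tab), n_iter=2)
        assert (grid["flag"] == "single-class").all()


class TestFeatureSweep:
    def test_deterministic_and_truncating(self, single_module_cohort):
        ds, ann, truth = single_module_cohort
        gsc = cg.generate_gmt(truth, n_decoy_sets=6, set_size_range=(20, 50), seed=2)
        from carcinogenome.projection import project_dataset

        pm = project_dataset(ds, gsc)
        a = cl.feature_sweep(pm, ds.meta, ann, sizes=[2, 5, 100], n_iter=3, n_trees=50, seed=4)
        b = cl.feature_sweep(pm, ds.meta, ann, sizes=[2, 5, 100], n_iter=3, n_trees=50, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert a["n_features"].iloc[-1] == pm.es.shape[0]  # truncated to available
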