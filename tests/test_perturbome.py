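import numpy as np
import pandas as pd
import pytest
from scipy import stats

import carcinogenome as cg
from carcinogenome import perturbome as pb
from carcinogenome.core import TScoreMatrix, ValidationError
from tests.conftest import make_dataset


def fisher_two_sided_oracle(a, b, c, d):
    """Two-sided Fisher p by enumerating all tables with fixed margins and
    summing point probabilities <= the observed one (conditional method)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(x, n, r1, c1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def toy_tscore_matrix():
    """6 instances, 3 genes; gene g0 significant in 5 instances, g1 in 4,
    g2 nowhere."""
    instances = [f"c{i}" for i in range(6)]
    genes = ["g0", "g1", "g2"]
    t = pd.DataFrame(3.0, index=genes, columns=instances)
    t.loc["g1"] = -3.0
    q = pd.DataFrame(1.0, index=genes, columns=instances)
    fc = pd.DataFrame(1.0, index=genes, columns=instances)
    q.loc["g0", instances[:5]] = 0.001
    fc.loc["g0", instances[:5]] = 2.0
    q.loc["g1", instances[:4]] = 0.001
    fc.loc["g1", instances[:4]] = 0.5  # down-regulated (fc <= 1/1.5)
    meta = pd.DataFrame({"instance": instances, "compound": instances,
                         "dose_level": None}).set_index("instance")
    return TScoreMatrix(t=t, q=q, fc=fc, instance_meta=meta)


class TestCompoundTScores:
    def test_treated_identical_to_controls_gives_zero_t(self):
        vals = np.tile(np.arange(4.0)[:, None], (1, 6))
        ds = make_dataset(vals, n_controls=2, compounds=["c1"] * 2 + ["c2"] * 2)
        tm = pb.compound_tscores(ds)
        np.testing.assert_allclose(tm.t.to_numpy(), 0.0)

    def test_single_time_equals_pooled_two_sample_t(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(30, 8))
        ds = make_dataset(vals, n_controls=4, compounds=["c1"] * 4)
        tm = pb.compound_tscores(ds)
        expected = stats.ttest_ind(vals[:, 4:], vals[:, :4], axis=1, equal_var=True)
        np.testing.assert_allclose(tm.t["c1"].to_numpy(), expected.statistic, rtol=1e-10)

    def test_planted_module_genes_dominate_ranking(self):
        spec = cg.CohortSpec(n_genes=300, n_compounds=8, module_size=30, n_moa_modules=2,
                             effect_size=2.0, noise_sd=0.1, dose_levels=("high",),
                             dose_response=(1.0,), times=(29.0,), seed=404)
        ds, ann, truth = cg.generate_cohort(spec)
        tm = pb.compound_tscores(ds, ann)
        responder, mods = next(
            (c, m) for c, m in truth.compound_modules.items() if m
        )
        module_genes = set(g for m in mods for g in truth.module_genes[m])
        col = tm.t[responder].abs().sort_values(ascending=False)
        top = set(col.index[: len(module_genes)])
        # all of the top-|module| t-scores are module genes
        assert top == module_genes

    def test_multi_dose_instances_get_one_column_each(self):
        spec = cg.CohortSpec(n_genes=100, n_compounds=4, n_moa_modules=1, module_size=10,
                             times=(29.0,), seed=3)
        ds, ann, _ = cg.generate_cohort(spec)
        tm = pb.compound_tscores(ds, ann)
        assert len(tm.instances) == 4 * 3
        assert all("@" in i for i in tm.instances)

    def test_time_confounded_with_treatment_flagged_undefined(self):
        # controls only at time 1, treated only at time 2 -> singular design
        vals = np.random.default_rng(1).normal(size=(5, 6))
        ds = make_dataset(vals, n_controls=3, compounds=["c1"] * 3)
        meta = ds.meta.copy()
        meta.loc[~meta["is_control"], "time"] = 2.0
        meta["control_group_id"] = "shared"
        ds2 = cg.ExpressionDataset(ds.values, meta)
        tm = pb.compound_tscores(ds2)
        assert tm.t["c1"].isna().all()


class TestSelectResponsiveGenes:
    def test_five_instance_threshold(self):
        tm = toy_tscore_matrix()
        tab = pb.select_responsive_genes(tm, q_max=0.01, fc_min=1.5, min_compounds=5)
        assert list(tab.index) == ["g0"]
        assert tab.loc["g0", "n_compounds_up"] == 5
        tab4 = pb.select_responsive_genes(tm, q_max=0.01, fc_min=1.5, min_compounds=4)
        assert set(tab4.index) == {"g0", "g1"}
        assert tab4.loc["g1", "n_compounds_down"] == 4

    def test_degenerate_thresholds_keep_everything(self):
        tm = toy_tscore_matrix()
        tab = pb.select_responsive_genes(tm, q_max=1.0, fc_min=1.0, min_compounds=1)
        assert set(tab.index) == {"g0", "g1", "g2"}

    def test_up_down_exclusive_for_unidirectional_modules(self, strong_cohort):
        ds, ann, truth = strong_cohort
        tm = pb.compound_tscores(ds, ann)
        tab = pb.select_responsive_genes(tm, min_compounds=2)
        active = truth.active_genes()
        planted = tab.loc[[g for g in tab.index if g in active]]
        assert (planted[["n_compounds_up", "n_compounds_down"]].min(axis=1) == 0).all()


class TestFisherEnrichment:
    def test_diagonal_table_matches_enumeration(self):
        # [[5,0],[0,5]]: two-sided p = 2/252
        _, p = stats.fisher_exact([[5, 0], [0, 5]], alternative="two-sided")
        assert p == pytest.approx(2 / 252, rel=1e-9)
        assert fisher_two_sided_oracle(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-9)

    def test_balanced_table_is_null(self):
        _, p = stats.fisher_exact([[2, 2], [2, 2]], alternative="two-sided")
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_small_tables_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 7, size=4)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert p == pytest.approx(fisher_two_sided_oracle(a, b, c, d), rel=1e-6)

    def test_gene_enrichment_flags_carcinogen_association(self, strong_cohort):
        ds, ann, truth = strong_cohort
        tm = pb.compound_tscores(ds, ann)
        tab = pb.select_responsive_genes(tm, min_compounds=2)
        enr = pb.gene_phenotype_enrichment(tm, tab, ann, "carcinogenic",
                                           q_max=0.01, fc_min=1.5)
        active = truth.active_genes()
        hits = enr[enr["fisher_q"] <= 0.05]
        assert len(hits) > 0
        assert set(hits.index) <= active

    def test_too_few_labelled_compounds_rejected(self, strong_cohort):
        ds, ann, _ = strong_cohort
        tm = pb.compound_tscores(ds, ann)
        tab = pb.select_responsive_genes(tm, min_compounds=2)
        lop = ann.table.copy()
        lop["carcinogenic"] = ["positive"] + ["unknown"] * (len(lop) - 1)
        with pytest.raises(ValidationError):
            pb.gene_phenotype_enrichment(tm, tab, cg.CompoundAnnotation(lop), "carcinogenic")


class TestClustering:
    def test_recovers_responder_split(self, single_module_cohort):
        from sklearn.metrics import adjusted_rand_score

        ds, ann, truth = single_module_cohort
        tm = pb.compound_tscores(ds, ann)
        clusters = pb.cluster_compounds(tm, k=2)
        cpd_of = tm.instance_meta["compound"]
        truth_labels = [bool(truth.compound_modules[cpd_of[i]]) for i in clusters.index]
        assert adjusted_rand_score(truth_labels, clusters.to_numpy()) > 0.9

    def test_duplicate_columns_cluster_together(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(20, 3))
        t = pd.DataFrame(
            np.hstack([base[:, [0]], base[:, [0]], base[:, [1]], base[:, [2]]]),
            index=[f"g{i}" for i in range(20)], columns=["a", "a2", "b", "c"],
        )
        meta = pd.DataFrame({"instance": t.columns, "compound": t.columns,
                             "dose_level": None}).set_index("instance")
        tm = TScoreMatrix(t=t, q=t.abs().clip(0, 1) * 0, fc=t * 0 + 1.0, instance_meta=meta)
        clusters = pb.cluster_compounds(tm, k=2)
        assert clusters["a"] == clusters["a2"]

    def test_column_permutation_invariance(self, strong_cohort):
        ds, ann, _ = strong_cohort
        tm = pb.compound_tscores(ds, ann)
        clusters = pb.cluster_compounds(tm)
        perm = list(reversed(tm.instances))
        tm_perm = TScoreMatrix(t=tm.t[perm], q=tm.q[perm], fc=tm.fc[perm],
                               instance_meta=tm.instance_meta.loc[perm])
        clusters_perm = pb.cluster_compounds(tm_perm)
        # same partition up to label swap
        agree = (clusters.sort_index() == clusters_perm.sort_index()).mean()
        assert agree in (0.0, 1.0) or agree > 0.99 or agree < 0.01

    def test_k_below_two_rejected(self, strong_cohort):
        ds, ann, _ = strong_cohort
        tm = pb.compound_tscores(ds, ann)
        with pytest.raises(ValidationError):
            pb.cluster_compounds(tm, k=1)

    def test_cluster_association_enriched_for_carcinogens(self, single_module_cohort):
        ds, ann, _ = single_module_cohort
        tm = pb.compound_tscores(ds, ann)
        clusters = pb.cluster_compounds(tm)
        p = pb.cluster_phenotype_association(clusters, tm, ann, "carcinogenic")
        assert p < 1e-3


class TestDEGCountTest:
    def test_identical_count_multisets_ks_zero(self):
        tm = toy_tscore_matrix()
        clusters = pd.Series([1, 2, 1, 2, 1, 2], index=tm.instances)
        stat, p, counts = pb.cluster_deg_count_test(tm, clusters, q_max=1.0, fc_min=1.0)
        assert counts.nunique() == 1  # all instances have the same count
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_ranges_ks_one(self, single_module_cohort):
        ds, ann, truth = single_module_cohort
        tm = pb.compound_tscores(ds, ann)
        clusters = pb.cluster_compounds(tm)
        stat, p, counts = pb.cluster_deg_count_test(tm, clusters)
        # responders have far more significant genes than inert compounds
        assert stat == pytest.approx(1.0)
        assert p < 1e-4

    def test_matches_permutation_oracle_on_small_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=6)
        y = rng.normal(loc=0.3, size=5)
        res = stats.ks_2samp(x, y)
        # permutation oracle for the KS statistic's tail probability
        pooled = np.concatenate([x, y])
        n_hits = 0
        n_perm = 3000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            s = stats.ks_2samp(pooled[:6], pooled[6:]).statistic
            n_hits += s >= res.statistic - 1e-12
        p_perm = n_hits / n_perm
        assert abs(res.pvalue - p_perm) < 4 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.02
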