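"""Transformation, RM-ANOVA, volcano, ROC, PLS-DA, PCA and HCA behavior."""

import itertools

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from sklearn.cross_decomposition import PLSRegression

from msimetab.feature_qc import FeatureMatrix
from msimetab.stats_suite import (AnalysisError, bonferroni, hca, pca_scores,
                                  plsda, preprocess, ratio_feature, rm_anova2,
                                  roc_auc, shapiro_wilk, volcano_paired)


def design_meta(n_subjects=6, times=(0, 60, 120), states=("naive", "trained")):
    rows = [{"subject": f"S{i}", "timepoint": t, "state": s,
             "is_qc": False, "run_id": f"r{i}"}
            for i in range(n_subjects) for s in states for t in times]
    return pd.DataFrame(rows)


class TestPreprocess:
    def test_columns_autoscaled(self, rng):
        df = pd.DataFrame(rng.lognormal(size=(20, 5)),
                          columns=list("abcde"))
        tm = preprocess(df)
        np.testing.assert_allclose(tm.values.mean(), 0, atol=1e-9)
        np.testing.assert_allclose(tm.values.std(ddof=1), 1, atol=1e-9)

    def test_decade_column_scales_to_unit_steps(self):
        # log10 of (1, 10, 100) is (0, 1, 2); autoscaling with the sample
        # SD (n-1) maps it to (-1, 0, 1)
        tm = preprocess(pd.DataFrame({"a": [1.0, 10.0, 100.0]}))
        np.testing.assert_allclose(tm.values["a"], [-1.0, 0.0, 1.0],
                                   atol=1e-12)

    def test_half_minimum_imputation(self):
        tm = preprocess(pd.DataFrame({"a": [0.0, 0.2, 2.0]}))
        assert tm.imputed["a"].tolist() == [True, False, False]
        # imputed cell saw 0.1 before the log: check via inverse transform
        back = 10 ** (tm.values["a"] * tm.feature_sds["a"]
                      + tm.feature_means["a"])
        assert back.iloc[0] == pytest.approx(0.1)

    def test_all_missing_feature_rejected(self):
        with pytest.raises(AnalysisError):
            preprocess(pd.DataFrame({"a": [np.nan, 0.0, -1.0]}))


class TestRmAnova2:
    def test_matches_independent_implementation(self, rng):
        meta = design_meta()
        vals = pd.DataFrame({
            "null": rng.normal(size=len(meta)),
            "timed": rng.normal(size=len(meta))
            + (meta["timepoint"] == 120) * 1.0,
            "trained": rng.normal(size=len(meta))
            + (meta["state"] == "trained") * 1.5,
        })
        rows = rm_anova2(vals, meta)
        df = pd.concat([meta, vals], axis=1)
        for row in rows:
            ref = pg.rm_anova(data=df, dv=row.metabolite_key,
                              within=["timepoint", "state"],
                              subject="subject", detailed=True)
            p_ref = ref["p_unc"].to_numpy()
            assert row.p_time == pytest.approx(p_ref[0], rel=1e-9)
            assert row.p_training == pytest.approx(p_ref[1], rel=1e-9)
            assert row.p_interaction == pytest.approx(p_ref[2], rel=1e-9)

    def test_planted_time_decrease_detected_and_directed(self, rng):
        meta = design_meta(n_subjects=11,
                           times=(0, 20, 30, 60, 90, 120))
        base = rng.normal(size=len(meta)) * 0.3
        effect = -1.5 * (meta["timepoint"] / 120.0)
        vals = pd.DataFrame({"leu_like": base + effect})
        row = rm_anova2(vals, meta, m_features=55)[0]
        assert row.p_adj_time < 0.05
        assert row.direction_time == "decrease"
        assert row.direction_training == "none"

    def test_constant_feature_is_no_effect_not_crash(self):
        meta = design_meta()
        vals = pd.DataFrame({"flat": np.ones(len(meta))})
        row = rm_anova2(vals, meta)[0]
        assert row.p_time == 1.0 and row.p_training == 1.0
        assert row.direction_time == "none"

    def test_bonferroni_adjustment_capped_and_ordered(self):
        assert bonferroni(0.01, 55) == pytest.approx(0.55)
        assert bonferroni(0.5, 55) == 1.0
        assert bonferroni(0.01, 55) >= 0.01

    def test_incomplete_layout_rejected(self, rng):
        meta = design_meta().iloc[:-1]
        vals = pd.DataFrame({"a": rng.normal(size=len(meta))})
        with pytest.raises(AnalysisError):
            rm_anova2(vals, meta)


def paired_matrix(values_by_state, subjects=None):
    states = list(values_by_state)
    n = len(next(iter(values_by_state.values())))
    subjects = subjects or [f"S{i}" for i in range(n)]
    meta = pd.DataFrame({
        "subject": subjects * len(states),
        "timepoint": [0] * n * len(states),
        "state": sum(([s] * n for s in states), []),
        "is_qc": [False] * n * len(states),
        "run_id": [f"r{i}" for i in range(n * len(states))],
    })
    vals = pd.DataFrame(
        {"f": np.concatenate([values_by_state[s] for s in states])})
    return FeatureMatrix(meta, vals)


class TestVolcano:
    def test_identical_groups_not_significant(self):
        x = np.full(8, 2.0)
        m = paired_matrix({"naive": x, "trained": x})
        rows = volcano_paired(m, "state", "trained", "naive")
        assert not rows[0].significant
        assert rows[0].fold_change == pytest.approx(1.0)

    def test_planted_twofold_decrease_flagged(self, rng):
        x = rng.lognormal(0, 0.05, size=11) * 4.0
        m = paired_matrix({"naive": x, "trained": x / 2.0})
        row = volcano_paired(m, "state", "trained", "naive")[0]
        assert row.fold_change == pytest.approx(0.5, rel=0.05)
        assert row.significant

    def test_fc_gate_blocks_small_changes(self, rng):
        x = rng.lognormal(0, 0.01, size=11) * 4.0
        m = paired_matrix({"naive": x, "trained": x / 1.4})
        row = volcano_paired(m, "state", "trained", "naive")[0]
        assert row.p_paired < 0.05  # highly consistent ...
        assert not row.significant  # ... but below the 1.5x fold gate

    def test_unpaired_subject_errors(self, rng):
        m = paired_matrix({"naive": rng.normal(5, 1, 4),
                           "trained": rng.normal(5, 1, 4)})
        m.meta.loc[7, "subject"] = "S9"
        with pytest.raises(AnalysisError, match="S"):
            volcano_paired(m, "state", "trained", "naive")


def brute_force_auc(cases, controls):
    wins = sum(1.0 if a > b else 0.5 if a == b else 0.0
               for a, b in itertools.product(cases, controls))
    return wins / (len(cases) * len(controls))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([5.0, 6.0, 7.0], [1.0, 2.0, 3.0])
        assert r.auc == 1.0 and r.orientation == "higher_in_case"

    def test_hand_counted_example(self):
        # pairs (3,1)+ (3,4)- (5,1)+ (5,4)+ -> 3 of 4
        r = roc_auc([3.0, 5.0], [1.0, 4.0])
        assert r.auc == pytest.approx(0.75)

    def test_orientation_flips_low_markers(self):
        r = roc_auc([1.0, 2.0, 3.0], [5.0, 6.0, 7.0])
        assert r.auc == 1.0 and r.orientation == "lower_in_case"

    def test_null_distribution_near_half(self, rng):
        r = roc_auc(rng.normal(size=400), rng.normal(size=400))
        assert abs(r.auc - 0.5) < 0.08
        assert r.p > 0.01

    def test_p_matches_scipy_asymptotic(self, rng):
        cases = rng.normal(0.8, 1, size=12)
        controls = rng.normal(0, 1, size=10)
        r = roc_auc(cases, controls)
        ref = sps.mannwhitneyu(cases, controls, use_continuity=False,
                               method="asymptotic",
                               alternative="two-sided")
        assert r.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(AnalysisError):
            roc_auc([], [1.0])

    @given(st.lists(st.integers(0, 5), min_size=1, max_size=8),
           st.lists(st.integers(0, 5), min_size=1, max_size=8))
    @settings(max_examples=300, deadline=None)
    def test_equals_brute_force_pair_counting(self, cases, controls):
        r = roc_auc(cases, controls)
        expected = brute_force_auc(cases, controls)
        assert r.auc == pytest.approx(max(expected, 1 - expected))


class TestRatioFeature:
    def matrix(self, rng):
        meta = design_meta(n_subjects=3, times=(0,), states=("naive",))
        vals = pd.DataFrame({"num": [2.0, 4.0, 8.0],
                             "den": [1.0, 2.0, 4.0]})
        return FeatureMatrix(meta, vals)

    def test_self_ratio_is_constant_zero(self, rng):
        m = self.matrix(rng)
        out, label = ratio_feature(m, "num", "num")
        assert (out.values[label] == 0).all()

    def test_doubled_numerator_constant_log2(self, rng):
        m = self.matrix(rng)
        out, label = ratio_feature(m, "num", "den")
        np.testing.assert_allclose(out.values[label], np.log10(2.0))
        assert label == "num/den"

    def test_missing_key_rejected(self, rng):
        with pytest.raises(AnalysisError):
            ratio_feature(self.matrix(rng), "num", "nope")


class TestPlsda:
    def separated_data(self, rng, n_per=25, p=50, shift=3.0, informative=5):
        X = rng.normal(size=(2 * n_per, p))
        labels = np.array(["a"] * n_per + ["b"] * n_per)
        X[labels == "b", :informative] += shift
        cols = [f"f{i:02d}" for i in range(p)]
        return pd.DataFrame(X, columns=cols), labels

    def test_separated_classes_fit_and_validate(self, rng):
        df, labels = self.separated_data(rng)
        m = plsda(df, labels)
        assert m.r2y > 0.9
        assert m.q2 > 0.5
        top5 = set(m.vip.sort_values(ascending=False).index[:5])
        assert top5 == {f"f{i:02d}" for i in range(5)}

    def test_vip_mean_square_is_one(self, rng):
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            df, labels = self.separated_data(r, n_per=8, p=12, shift=1.0)
            m = plsda(df, labels)
            assert (m.vip ** 2).mean() == pytest.approx(1.0, abs=1e-6)

    def test_permuted_labels_not_predictive(self, rng):
        df, labels = self.separated_data(rng, n_per=10, p=20)
        q2s = []
        for seed in range(9):
            perm = np.random.default_rng(seed).permutation(labels)
            q2s.append(plsda(df, perm).q2)
        assert np.median(q2s) <= 0

    def test_matches_sklearn_pls_fit(self, rng):
        df, labels = self.separated_data(rng, n_per=10, p=8)
        m = plsda(df, labels, n_components=2)
        X = df.to_numpy()
        y = (labels == "b").astype(float)
        sk = PLSRegression(n_components=2, scale=False).fit(
            X - X.mean(0), y - y.mean())
        yhat = sk.predict(X - X.mean(0)).ravel() + y.mean()
        r2_sk = 1 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert m.r2y == pytest.approx(r2_sk, abs=1e-9)

    def test_full_rank_components_reproduce_ols(self, rng):
        X = rng.normal(size=(8, 3))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        m = plsda(pd.DataFrame(X), labels, n_components=3)
        y = (labels == "b").astype(float)
        import statsmodels.api as sm
        ols = sm.OLS(y, sm.add_constant(X)).fit()
        assert m.r2y == pytest.approx(ols.rsquared, abs=1e-6)
        assert m.q2 <= m.r2y

    def test_too_few_samples_per_class(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 3)))
        with pytest.raises(AnalysisError):
            plsda(df, np.array(["a", "a", "b", "b"]))


class TestPcaHca:
    def test_duplicated_rows_identical_scores(self, rng):
        X = rng.normal(size=(6, 4))
        X[3] = X[0]
        scores, _ = pca_scores(pd.DataFrame(X))
        np.testing.assert_allclose(scores.iloc[0], scores.iloc[3],
                                   atol=1e-12)

    def test_explained_variance_sums_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        _, explained = pca_scores(df, n_components=4)
        assert explained.sum() == pytest.approx(1.0)

    def test_qc_rows_cluster_tighter_than_study_rows(self, rng):
        study = rng.normal(0, 1.0, size=(20, 10))
        qc = rng.normal(0, 0.1, size=(8, 10))
        scores, _ = pca_scores(pd.DataFrame(np.vstack([study, qc])))
        from scipy.spatial.distance import pdist
        d_study = pdist(scores.iloc[:20]).mean()
        d_qc = pdist(scores.iloc[20:]).mean()
        assert d_qc < d_study

    def test_identical_rows_merge_first_at_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        res = hca(pd.DataFrame(X), labels=["a", "b", "c"])
        assert res.linkage_matrix[0, 2] == pytest.approx(0.0)
        assert set(res.linkage_matrix[0, :2].astype(int)) == {0, 1}

    def test_two_planted_clusters_bipartition(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(5, 3)),
                       rng.normal(10, 0.1, size=(5, 3))])
        res = hca(pd.DataFrame(X))
        order = res.leaf_order
        assert {frozenset(order[:5]), frozenset(order[5:])} == \
            {frozenset(range(5)), frozenset(range(5, 10))}

    def test_single_row_tree(self):
        res = hca(pd.DataFrame([[1.0, 2.0]]), labels=["only"])
        assert res.to_newick() == "only;"

    def test_newick_export_parses(self, rng):
        import io
        from Bio import Phylo
        X = rng.normal(size=(5, 3))
        res = hca(pd.DataFrame(X), labels=[f"L{i}" for i in range(5)])
        tree = Phylo.read(io.StringIO(res.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == \
            [f"L{i}" for i in range(5)]


def test_shapiro_wilk_utility(rng):
    w, p = shapiro_wilk(rng.normal(size=50))
    assert 0 < w <= 1 and p > 0.001
    with pytest.raises(AnalysisError):
        shapiro_wilk([1.0, 2.0])
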