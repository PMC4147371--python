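"""Predictor panel assembly, OLS fitting, LOOCV Q^2 and stepwise selection."""

import numpy as np
import pandas as pd
import pytest

from msimetab.feature_qc import FeatureMatrix
from msimetab.prognostic import (PanelError, PredictorPanel,
                                 RankDeficiencyError, build_panel, fit_mlr,
                                 loocv_q2, stepwise_select)


def naive_matrix(responses):
    """responses: {key: {(subject, timepoint): value}}"""
    pairs = sorted({pair for vals in responses.values() for pair in vals})
    meta = pd.DataFrame({
        "subject": [s for s, _ in pairs],
        "timepoint": [t for _, t in pairs],
        "state": ["naive"] * len(pairs),
        "is_qc": [False] * len(pairs),
        "run_id": ["r"] * len(pairs),
    })
    vals = pd.DataFrame({k: [v.get(p, np.nan) for p in pairs]
                         for k, v in responses.items()})
    return FeatureMatrix(meta, vals)


class TestBuildPanel:
    def test_three_variables_per_metabolite(self):
        m = naive_matrix({"met": {("S1", 0): 2.0, ("S1", 120): 1.0,
                                  ("S2", 0): 4.0, ("S2", 120): 3.0}})
        panel = build_panel(m, ["met"])
        assert panel.variables == ["met@0", "met@120", "met@120/0"]
        assert panel.design_matrix.loc["S1", "met@0"] == \
            pytest.approx(np.log10(2.0))
        assert panel.design_matrix.loc["S2", "met@120/0"] == \
            pytest.approx(np.log10(3.0 / 4.0))
        assert panel.variable_kinds["met@120/0"] == "ratio_120_over_0"

    def test_named_ratio_adds_both_timepoints(self):
        m = naive_matrix({
            "tml": {("S1", 0): 2.0, ("S1", 120): 4.0,
                    ("S2", 0): 1.0, ("S2", 120): 8.0},
            "ss": {("S1", 0): 1.0, ("S1", 120): 2.0,
                   ("S2", 0): 4.0, ("S2", 120): 2.0},
        })
        panel = build_panel(m, [], named_ratios=[("tml", "ss")])
        assert "tml/ss@0" in panel.variables
        assert "tml/ss@120" in panel.variables
        assert panel.design_matrix.loc["S1", "tml/ss@0"] == \
            pytest.approx(np.log10(2.0))

    def test_constant_column_dropped_with_warning(self):
        m = naive_matrix({"met": {("S1", 0): 2.0, ("S1", 120): 2.0,
                                  ("S2", 0): 2.0, ("S2", 120): 4.0}})
        with pytest.warns(UserWarning, match="constant"):
            panel = build_panel(m, ["met"])
        assert "met@0" not in panel.variables

    def test_missing_timepoint_names_subject(self):
        m = naive_matrix({"met": {("S1", 0): 2.0, ("S1", 120): 1.0,
                                  ("S2", 0): 4.0}})
        with pytest.raises(PanelError, match="S2"):
            build_panel(m, ["met"])


class TestFitMlr:
    def test_exact_linear_relation_recovered(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0]},
                         index=list("abcde"))
        y = pd.Series([1.0, 3.0, 5.0, 7.0, 9.0], index=list("abcde"))
        model = fit_mlr(X, y)
        assert model.r2 == pytest.approx(1.0)
        assert model.coefficients["x"] == pytest.approx(2.0)
        assert model.coefficients["intercept"] == pytest.approx(1.0)

    def test_planted_coefficients_recovered_at_scale(self, rng):
        n, p = 40, 8
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"v{i}" for i in range(p)])
        beta = np.array([1.5, -2.0, 0.8, 0.0, 1.0, -0.5, 2.5, 0.3])
        y = pd.Series(X.to_numpy() @ beta + rng.normal(0, 0.5, size=n))
        hits = 0
        model = fit_mlr(X, y)
        import statsmodels.api as sm
        res = sm.OLS(y, sm.add_constant(X)).fit()
        lo, hi = res.conf_int().loc[[f"v{i}" for i in range(p)]].to_numpy().T
        hits = ((beta >= lo) & (beta <= hi)).sum()
        assert hits >= 7  # 95% CIs cover the truth for most coefficients

    def test_null_relation_low_r2(self, rng):
        r2s = []
        for seed in range(7):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(30, 3)))
            y = pd.Series(r.normal(size=30))
            r2s.append(fit_mlr(X, y).r2)
        assert np.median(r2s) < 0.3

    def test_collinear_columns_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                          "b": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]})
        y = pd.Series([1.0, 2.0, 1.0, 2.0, 1.0, 2.0])
        with pytest.raises(RankDeficiencyError):
            fit_mlr(X, y)

    def test_overparameterized_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        with pytest.raises(RankDeficiencyError):
            fit_mlr(X, pd.Series(rng.normal(size=5)))


class TestLoocvQ2:
    def test_perfect_linear_relation(self):
        X = pd.DataFrame({"x": np.arange(6.0)})
        y = pd.Series(2.0 * np.arange(6.0) + 1.0)
        q2, preds = loocv_q2(X, y)
        assert q2 == pytest.approx(1.0)
        np.testing.assert_allclose(preds, y, atol=1e-9)

    def test_shuffled_response_not_predictive(self, rng):
        q2s = []
        X = pd.DataFrame(rng.normal(size=(15, 3)))
        y = pd.Series(X.iloc[:, 0] * 2.0 + rng.normal(0, 0.1, 15))
        for seed in range(9):
            perm = np.random.default_rng(seed).permutation(y.to_numpy())
            q2s.append(loocv_q2(X, pd.Series(perm, index=y.index))[0])
        assert np.median(q2s) <= 0

    def test_minimal_n3_matches_hand_folds(self):
        """Each fold is a 2-point OLS: the line through the other two."""
        X = pd.DataFrame({"x": [0.0, 1.0, 3.0]}, index=["a", "b", "c"])
        y = pd.Series([0.0, 2.0, 3.0], index=["a", "b", "c"])
        q2, preds = loocv_q2(X, y)
        # leave out a: line through (1,2),(3,3): y = 1.5 + 0.5x -> 1.5 at 0
        # leave out b: line through (0,0),(3,3): y = x -> 1 at 1
        # leave out c: line through (0,0),(1,2): y = 2x -> 6 at 3
        np.testing.assert_allclose(preds[["a", "b", "c"]],
                                   [1.5, 1.0, 6.0], atol=1e-9)
        tss = ((y - y.mean()) ** 2).sum()
        press = (1.5 - 0) ** 2 + (1 - 2) ** 2 + (6 - 3) ** 2
        assert q2 == pytest.approx(1 - press / tss)

    def test_q2_never_exceeds_r2(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(12, 2)))
            y = pd.Series(X.iloc[:, 0] + r.normal(0, 0.5, 12))
            q2, _ = loocv_q2(X, y)
            assert q2 <= fit_mlr(X, y).r2 + 1e-12


class TestStepwise:
    def panel_with_signal(self, rng, n=20, noise_vars=20):
        X = pd.DataFrame(
            rng.normal(size=(n, noise_vars + 1)),
            columns=["signal"] + [f"noise{i:02d}" for i in range(noise_vars)],
            index=[f"S{i}" for i in range(n)])
        y = pd.Series(3.0 * X["signal"] + rng.normal(0, 0.3, n),
                      index=X.index)
        return PredictorPanel(design_matrix=X), y

    def test_informative_variable_selected_first(self, rng):
        panel, y = self.panel_with_signal(rng)
        model = stepwise_select(panel, y, max_vars=3)
        assert model.selected[0] == "signal"
        assert model.q2 > 0.5

    def test_max_vars_one_respected(self, rng):
        panel, y = self.panel_with_signal(rng)
        model = stepwise_select(panel, y, max_vars=1)
        assert len(model.selected) == 1

    def test_selection_invariant_to_column_order(self, rng):
        panel, y = self.panel_with_signal(rng, n=15, noise_vars=6)
        model_fwd = stepwise_select(panel, y, max_vars=3)
        reversed_panel = PredictorPanel(
            design_matrix=panel.design_matrix[panel.design_matrix.columns[::-1]])
        model_rev = stepwise_select(reversed_panel, y, max_vars=3)
        assert model_fwd.selected == model_rev.selected
        assert model_fwd.q2 == pytest.approx(model_rev.q2)

    def test_pure_noise_returns_interceptish_model(self, rng):
        X = pd.DataFrame(rng.normal(size=(12, 5)),
                         columns=list("abcde"))
        y = pd.Series(rng.normal(size=12))
        model = stepwise_select(PredictorPanel(design_matrix=X), y,
                                max_vars=4)
        assert model.q2 <= 0.5  # no planted structure to find

    def test_q2_le_r2(self, rng):
        panel, y = self.panel_with_signal(rng, n=15, noise_vars=4)
        model = stepwise_select(panel, y, max_vars=3)
        assert model.q2 <= model.r2 + 1e-12


class TestNoiseColumnsDoNotHelp:
    def test_extra_noise_columns_do_not_raise_final_q2_in_expectation(self):
        """Appending pure-noise candidates to the pool should not improve
        the selected model's LOOCV Q^2 on average over seeds."""
        deltas = []
        for seed in range(6):
            rng = np.random.default_rng(300 + seed)
            n = 18
            X = pd.DataFrame(
                rng.normal(size=(n, 5)),
                columns=["signal"] + [f"n{i}" for i in range(4)],
                index=[f"S{i}" for i in range(n)])
            y = pd.Series(2.5 * X["signal"] + rng.normal(0, 0.4, n),
                          index=X.index)
            base = stepwise_select(PredictorPanel(design_matrix=X), y,
                                   max_vars=3)
            extra = X.copy()
            for j in range(5):
                extra[f"x{j}"] = rng.normal(size=n)
            aug = stepwise_select(PredictorPanel(design_matrix=extra), y,
                                  max_vars=3)
            deltas.append(aug.q2 - base.q2)
        assert np.mean(deltas) <= 0.02
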