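"""Prognostic multiple linear regression for glucose-tolerance changes.

Predicts each subject's training-induced change in 2-h post-load glucose
(delta 2hPG, mM) from baseline (untrained-state) metabolite variables:
log responses at 0 and 120 min and their 120/0 log-ratio, plus named
ratiometric markers.  The model is refined by forward stepwise selection
that maximizes the leave-one-out cross-validated Q^2, the criterion that
can actually drive a stopping rule (R^2 is monotone in the number of
variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .feature_qc import FeatureMatrix


class PanelError(ValueError):
    pass


class RankDeficiencyError(ValueError):
    pass


@dataclass
class PredictorPanel:
    """Subjects x candidate-variable design matrix, all on the log scale."""

    design_matrix: pd.DataFrame  # index: subject_id
    variable_kinds: dict[str, str] = field(default_factory=dict)

    @property
    def variables(self) -> list[str]:
        return list(self.design_matrix.columns)


@dataclass
class PrognosticModel:
    selected: list[str]
    coefficients: pd.Series   # includes "intercept"
    r2: float
    q2: float
    per_coefficient_p: pd.Series
    loocv_predictions: pd.Series

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "coefficients": {k: float(v)
                             for k, v in self.coefficients.items()},
            "r2": float(self.r2),
            "q2": float(self.q2),
            "p_values": {k: float(v)
                         for k, v in self.per_coefficient_p.items()},
            "loocv_predictions": {str(k): float(v)
                                  for k, v in self.loocv_predictions.items()},
        }


def build_panel(
    matrix_naive: FeatureMatrix,
    candidate_keys: Sequence[str],
    named_ratios: Sequence[tuple[str, str]] = (),
    t0: int = 0,
    t_end: int = 120,
) -> PredictorPanel:
    """Assemble baseline predictor variables from the naive-state matrix.

    For each candidate feature three variables are generated per subject:
    ``key@0`` and ``key@120`` (log10 response at the two anchor timepoints)
    and ``key@120/0`` (their log-ratio).  Each named ratio (num, den) adds a
    log-ratio column at both timepoints.  Constant columns are dropped with
    a warning.
    """
    meta, vals = matrix_naive.meta, matrix_naive.values
    study = ~matrix_naive.qc_mask

    def timepoint_values(key: str, tp: int) -> pd.Series:
        sel = study & (meta["timepoint"] == tp)
        if key not in vals.columns:
            raise PanelError(f"candidate {key} not in matrix")
        s = vals.loc[sel, key]
        s.index = meta.loc[sel, "subject"]
        if s.isna().any() or (s <= 0).any():
            bad = s.index[s.isna() | (s <= 0)].tolist()
            raise PanelError(
                f"{key} at {tp} min missing/non-positive for {bad}")
        return s.sort_index()

    columns: dict[str, pd.Series] = {}
    kinds: dict[str, str] = {}
    for key in candidate_keys:
        v0 = np.log10(timepoint_values(key, t0))
        v1 = np.log10(timepoint_values(key, t_end))
        columns[f"{key}@{t0}"] = v0
        kinds[f"{key}@{t0}"] = "single_0min"
        columns[f"{key}@{t_end}"] = v1
        kinds[f"{key}@{t_end}"] = "single_120min"
        columns[f"{key}@{t_end}/{t0}"] = v1 - v0
        kinds[f"{key}@{t_end}/{t0}"] = "ratio_120_over_0"
    for num, den in named_ratios:
        for tp in (t0, t_end):
            lab = f"{num}/{den}@{tp}"
            columns[lab] = (np.log10(timepoint_values(num, tp))
                            - np.log10(timepoint_values(den, tp)))
            kinds[lab] = "named_ratio"

    design = pd.DataFrame(columns)
    if design.isna().any().any():
        missing = {subj for col in design.columns
                   for subj in design.index[design[col].isna()]}
        raise PanelError(
            f"subjects missing an anchor timepoint: {sorted(missing)}")
    constant = [c for c in design.columns if design[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant predictor columns: {constant}")
        design = design.drop(columns=constant)
        for c in constant:
            kinds.pop(c, None)
    return PredictorPanel(design_matrix=design, variable_kinds=kinds)


def fit_mlr(X: pd.DataFrame, y: pd.Series) -> PrognosticModel:
    """Ordinary least squares with per-coefficient two-sided t-tests."""
    X = pd.DataFrame(X)
    y = pd.Series(y).loc[X.index]
    if X.shape[0] <= X.shape[1] + 1:
        raise RankDeficiencyError(
            f"{X.shape[0]} rows cannot support {X.shape[1]} predictors")
    design = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax() if X.shape[1] > 1 else (X.columns[0],)
        raise RankDeficiencyError(
            f"design matrix is rank deficient (near-collinear: {worst})")
    res = sm.OLS(y, design).fit()
    coefs = res.params.rename({"const": "intercept"})
    pvals = res.pvalues.rename({"const": "intercept"})
    return PrognosticModel(
        selected=list(X.columns), coefficients=coefs,
        r2=float(res.rsquared), q2=float("nan"),
        per_coefficient_p=pvals,
        loocv_predictions=pd.Series(dtype=float))


def loocv_q2(
    X: pd.DataFrame, y: pd.Series, selected: Sequence[str] | None = None,
) -> tuple[float, pd.Series]:
    """Leave-one-out Q^2 = 1 - PRESS/TSS with per-fold refitting.

    Returns the Q^2 and the per-subject out-of-fold predictions.
    """
    X = pd.DataFrame(X)
    if selected is not None:
        X = X[list(selected)]
    y = pd.Series(y).loc[X.index]
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    yv = y.to_numpy(dtype=float)
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        beta, _, rank, _ = np.linalg.lstsq(design[mask], yv[mask],
                                           rcond=None)
        if rank < design.shape[1]:
            mask[i] = True
            raise RankDeficiencyError(
                f"rank-deficient refit when leaving out {y.index[i]}")
        preds[i] = design[i] @ beta
        mask[i] = True
    preds = pd.Series(preds, index=y.index)
    tss = float(((yv - yv.mean()) ** 2).sum())
    press = float(((yv - preds.to_numpy()) ** 2).sum())
    q2 = 1.0 - press / tss if tss > 0 else float("nan")
    return q2, preds


def stepwise_select(
    panel: PredictorPanel,
    y: pd.Series,
    max_vars: int = 8,
) -> PrognosticModel:
    """Forward stepwise selection maximizing leave-one-out Q^2.

    At each step the candidate variable whose addition most improves Q^2
    joins the model; selection stops when no candidate improves it or
    ``max_vars`` is reached.  Ties break on the lexicographically smaller
    label, making selection deterministic and column-order invariant.
    """
    X = panel.design_matrix
    y = pd.Series(y).loc[X.index]
    n = len(y)
    if n - max_vars < 3:
        warnings.warn(
            f"{max_vars} variables on {n} subjects is near-saturated; "
            "cross-validated statistics will be fragile")

    selected: list[str] = []
    tss = float(((y - y.mean()) ** 2).sum())
    # intercept-only LOOCV baseline
    base_preds = pd.Series(
        {idx: y.drop(idx).mean() for idx in y.index}, dtype=float)
    best_q2 = 1.0 - float(((y - base_preds) ** 2).sum()) / tss
    best_preds = base_preds

    while len(selected) < min(max_vars, len(X.columns)):
        candidates = []
        for var in X.columns:
            if var in selected:
                continue
            trial = selected + [var]
            if n - len(trial) < 2:
                continue
            try:
                q2, preds = loocv_q2(X, y, trial)
            except RankDeficiencyError:
                continue
            candidates.append((q2, var, preds))
        if not candidates:
            break
        candidates.sort(key=lambda c: (-c[0], c[1]))
        top_q2, top_var, top_preds = candidates[0]
        if top_q2 <= best_q2:
            break
        selected.append(top_var)
        best_q2, best_preds = top_q2, top_preds

    if not selected:
        warnings.warn("no variable improves on the intercept-only model")
        mean = float(y.mean())
        return PrognosticModel(
            selected=[], coefficients=pd.Series({"intercept": mean}),
            r2=0.0, q2=best_q2,
            per_coefficient_p=pd.Series({"intercept": float("nan")}),
            loocv_predictions=best_preds)

    model = fit_mlr(X[selected], y)
    model.q2 = best_q2
    model.loocv_predictions = best_preds
    return model
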