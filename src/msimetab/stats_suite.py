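"""Metabolite-level statistical battery for the cross-over OGTT study.

Implements the transformations and tests used to classify plasma features
by post-prandial time course and training status: log10 + autoscaling with
half-minimum imputation, repeated-measures two-way ANOVA with Bonferroni
correction, paired-volcano screening, rank-based ROC/AUC with the
Mann-Whitney normal approximation, ratiometric markers, NIPALS PLS-DA with
VIP scores and leave-one-out Q^2, PCA scores, and Ward hierarchical
clustering.

The repeated-measures ANOVA treats both factors (OGTT timepoint, 6 levels;
training state, 2 levels) as within-subject, with the subject-by-factor
interactions as the error strata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree

from .feature_qc import FeatureMatrix


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------

@dataclass
class TransformedMatrix:
    """Log10-transformed, autoscaled feature data with imputation record."""

    values: pd.DataFrame
    imputed: pd.DataFrame  # boolean mask of imputed cells
    feature_means: pd.Series  # post-log means used for scaling
    feature_sds: pd.Series


def preprocess(matrix: FeatureMatrix | pd.DataFrame) -> TransformedMatrix:
    """Half-minimum imputation, log10, then per-feature autoscaling.

    Missing or non-positive cells are replaced with half the smallest
    positive observed value of that feature before the log; each column is
    then centred and scaled to unit sample SD (n-1).
    """
    raw = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    raw = raw.astype(float)
    filled = raw.where(raw > 0)
    imputed = filled.isna()
    for col in filled.columns:
        if filled[col].notna().sum() == 0:
            raise AnalysisError(
                f"feature {col} has no positive values; filter it first")
        filled[col] = filled[col].fillna(filled[col].min() / 2.0)
    logged = np.log10(filled)
    mu = logged.mean()
    sd = logged.std(ddof=1)
    sd_safe = sd.replace(0, 1.0)
    scaled = (logged - mu) / sd_safe
    return TransformedMatrix(values=scaled, imputed=imputed,
                             feature_means=mu, feature_sds=sd)


# ---------------------------------------------------------------------------
# Repeated-measures two-way ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaRow:
    metabolite_key: str
    p_time: float
    p_training: float
    p_interaction: float
    p_adj_time: float
    p_adj_training: float
    p_adj_interaction: float
    direction_time: str      # increase | decrease | none
    direction_training: str


def bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def rm_anova2(
    tm: TransformedMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    m_features: int | None = None,
    alpha: float = 0.05,
) -> list[AnovaRow]:
    """Per-feature repeated-measures two-way ANOVA (time x training).

    Requires a complete subject x timepoint x state layout with one
    observation per cell.  Each main effect is tested against its
    subject-by-factor interaction; the time-by-training interaction against
    the three-way residual.  Bonferroni adjustment multiplies by
    ``m_features`` (default: the number of features tested).  Directions
    are the sign of (last vs first timepoint) and (second vs first state),
    reported only for effects significant after adjustment.
    """
    values = tm.values if isinstance(tm, TransformedMatrix) else tm
    subjects = np.sort(meta["subject"].unique())
    times = np.sort(meta["timepoint"].unique())
    states = pd.unique(meta["state"])  # keep given order (naive first)
    n_s, n_a, n_b = len(subjects), len(times), len(states)
    if n_s < 2:
        raise AnalysisError("repeated-measures ANOVA needs >= 2 subjects")
    if n_a < 2 or n_b < 2:
        raise AnalysisError("both factors need >= 2 levels")

    frame = values.copy()
    frame.index = pd.MultiIndex.from_frame(
        meta[["subject", "timepoint", "state"]])
    full = pd.MultiIndex.from_product([subjects, times, states],
                                      names=frame.index.names)
    try:
        frame = frame.loc[full]
    except KeyError as exc:
        raise AnalysisError("incomplete subject x time x state layout") from exc
    if len(frame) != len(full):
        raise AnalysisError("duplicate cells in design")

    n_feat = frame.shape[1]
    Y = frame.to_numpy().reshape(n_s, n_a, n_b, n_feat)

    grand = Y.mean(axis=(0, 1, 2))
    m_s = Y.mean(axis=(1, 2))          # subject means      (n_s, f)
    m_a = Y.mean(axis=(0, 2))          # time means         (n_a, f)
    m_b = Y.mean(axis=(0, 1))          # state means        (n_b, f)
    m_sa = Y.mean(axis=2)              # (n_s, n_a, f)
    m_sb = Y.mean(axis=1)              # (n_s, n_b, f)
    m_ab = Y.mean(axis=0)              # (n_a, n_b, f)

    ss_a = n_s * n_b * ((m_a - grand) ** 2).sum(axis=0)
    ss_b = n_s * n_a * ((m_b - grand) ** 2).sum(axis=0)
    ss_ab = n_s * ((m_ab - m_a[:, None, :] - m_b[None, :, :]
                    + grand) ** 2).sum(axis=(0, 1))
    ss_sa = n_b * ((m_sa - m_s[:, None, :] - m_a[None, :, :]
                    + grand) ** 2).sum(axis=(0, 1))
    ss_sb = n_a * ((m_sb - m_s[:, None, :] - m_b[None, :, :]
                    + grand) ** 2).sum(axis=(0, 1))
    ss_res = ((Y - m_sa[:, :, None, :] - m_sb[:, None, :, :]
               - m_ab[None, :, :, :] + m_s[:, None, None, :]
               + m_a[None, :, None, :] + m_b[None, None, :, :]
               - grand) ** 2).sum(axis=(0, 1, 2))

    df_a, df_b = n_a - 1, n_b - 1
    df_ab = df_a * df_b
    df_sa, df_sb = (n_s - 1) * df_a, (n_s - 1) * df_b
    df_res = (n_s - 1) * df_ab

    def f_test(ss_eff, df_eff, ss_err, df_err):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_eff / df_eff) / (ss_err / df_err)
        p = stats.f.sf(f, df_eff, df_err)
        return np.where(np.isfinite(f), p, 1.0)

    p_a = f_test(ss_a, df_a, ss_sa, df_sa)
    p_b = f_test(ss_b, df_b, ss_sb, df_sb)
    p_ab = f_test(ss_ab, df_ab, ss_res, df_res)

    m = m_features if m_features is not None else n_feat
    diff_time = m_a[-1] - m_a[0]
    diff_state = m_b[-1] - m_b[0]

    rows = []
    for j, key in enumerate(frame.columns):
        adj_t = bonferroni(p_a[j], m)
        adj_b = bonferroni(p_b[j], m)
        rows.append(AnovaRow(
            metabolite_key=str(key),
            p_time=float(p_a[j]), p_training=float(p_b[j]),
            p_interaction=float(p_ab[j]),
            p_adj_time=adj_t, p_adj_training=adj_b,
            p_adj_interaction=bonferroni(p_ab[j], m),
            direction_time=("none" if adj_t >= alpha else
                            "increase" if diff_time[j] > 0 else "decrease"),
            direction_training=("none" if adj_b >= alpha else
                                "increase" if diff_state[j] > 0
                                else "decrease"),
        ))
    return rows


# ---------------------------------------------------------------------------
# Paired volcano
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VolcanoRow:
    metabolite_key: str
    fold_change: float
    p_paired: float
    significant: bool


def volcano_paired(
    matrix: FeatureMatrix,
    factor: str,
    case,
    control,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.05,
) -> list[VolcanoRow]:
    """Paired case-vs-control screen with fold-change and t-test gates.

    The fold change is the ratio of raw group means (case/control); the
    p-value is a paired t-test on log10 values, paired by subject.  A
    feature is significant when FC > ``fc_thresh`` or < 1/``fc_thresh`` and
    p < ``p_thresh``.
    """
    meta, vals = matrix.meta, matrix.values
    sel_case = (~matrix.qc_mask) & (meta[factor] == case)
    sel_ctrl = (~matrix.qc_mask) & (meta[factor] == control)
    case_df = vals[sel_case].set_index(meta.loc[sel_case, "subject"])
    ctrl_df = vals[sel_ctrl].set_index(meta.loc[sel_ctrl, "subject"])
    case_df = case_df.groupby(level=0).mean().sort_index()
    ctrl_df = ctrl_df.groupby(level=0).mean().sort_index()
    unpaired = set(case_df.index) ^ set(ctrl_df.index)
    if unpaired:
        raise AnalysisError(f"unpaired subjects: {sorted(unpaired)}")

    rows = []
    for key in matrix.feature_keys:
        a, b = case_df[key], ctrl_df[key]
        mask = a.notna() & b.notna()
        a, b = a[mask], b[mask]
        fc = float(a.mean() / b.mean()) if b.mean() > 0 else float("inf")
        if len(a) >= 2 and not np.allclose(np.log10(a), np.log10(b)):
            _, p = stats.ttest_rel(np.log10(a), np.log10(b))
            p = float(p)
        else:
            p = 1.0
        sig = (fc > fc_thresh or fc < 1.0 / fc_thresh) and p < p_thresh
        rows.append(VolcanoRow(key, fc, p, sig))
    return rows


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    label: str
    auc: float
    p: float
    orientation: str  # higher_in_case | lower_in_case


def roc_auc(cases: Sequence[float], controls: Sequence[float],
            label: str = "") -> RocResult:
    """Rank-based ROC AUC with the tie-corrected Mann-Whitney normal test.

    AUC = U / (n1*n2) with ties counted one half; the reported AUC is
    oriented to be >= 0.5 and the orientation recorded.  The p-value is the
    two-sided normal approximation to the Mann-Whitney U statistic with tie
    correction (no continuity correction).
    """
    x = np.asarray(cases, dtype=float)
    y = np.asarray(controls, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    auc = u1 / (n1 * n2)
    orientation = "higher_in_case"
    if auc < 0.5:
        auc = 1.0 - auc
        orientation = "lower_in_case"

    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                if n > 1 else 0.0)
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        p = 1.0
    else:
        z = (u1 - n1 * n2 / 2.0) / np.sqrt(var_u)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return RocResult(label=label, auc=float(auc), p=p,
                     orientation=orientation)


def ratio_feature(
    matrix: FeatureMatrix, numerator: str, denominator: str,
    label: str | None = None,
) -> tuple[FeatureMatrix, str]:
    """Add a log10 ratiometric feature (numerator/denominator) column.

    Returns the augmented matrix and the derived column's label.  The
    derived column is already on the log scale, unlike raw RPA columns.
    """
    for key in (numerator, denominator):
        if key not in matrix.values.columns:
            raise AnalysisError(f"feature {key} not in matrix")
    den = matrix.values[denominator]
    if (den <= 0).any():
        raise AnalysisError(f"non-positive denominator values in {denominator}")
    label = label or f"{numerator}/{denominator}"
    values = matrix.values.copy()
    values[label] = np.log10(matrix.values[numerator] / den)
    return FeatureMatrix(matrix.meta.copy(), values), label


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsModel:
    n_components: int
    x_weights: np.ndarray    # (features, comps)
    x_loadings: np.ndarray   # (features, comps)
    y_loadings: np.ndarray   # (comps,)
    x_scores: np.ndarray     # (samples, comps)
    r2y: float
    q2: float
    vip: pd.Series
    classes: tuple
    feature_keys: list[str] = field(default_factory=list)


def _nipals_pls1(X: np.ndarray, y: np.ndarray, n_components: int):
    """Sequential NIPALS extraction for a single response column.

    Returns weights W, loadings P, y-loadings q, scores T on the centred
    inputs.
    """
    n, p = X.shape
    Xr = X.copy()
    yr = y.astype(float).copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = Xr.T @ yr
        norm = np.linalg.norm(w)
        if norm == 0:
            W, P, T = W[:, :a], P[:, :a], T[:, :a]
            q = q[:a]
            break
        w /= norm
        t = Xr @ w
        tt = t @ t
        if tt == 0:
            W, P, T = W[:, :a], P[:, :a], T[:, :a]
            q = q[:a]
            break
        p_a = Xr.T @ t / tt
        q_a = yr @ t / tt
        Xr = Xr - np.outer(t, p_a)
        yr = yr - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
    return W, P, q, T


def _pls_coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray):
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def plsda(
    tm: TransformedMatrix | pd.DataFrame,
    labels: Sequence,
    n_components: int = 2,
) -> PlsModel:
    """Two-class PLS-DA by NIPALS with VIP scores and leave-one-out Q^2.

    The class label is dummy-coded and centred; R^2Y is the cumulative
    explained label variance, Q^2 = 1 - PRESS/TSS with the model (including
    centring) refit on each leave-one-out fold.
    """
    values = tm.values if isinstance(tm, TransformedMatrix) else tm
    X = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(pd.unique(labels))
    if len(classes) != 2:
        raise AnalysisError("PLS-DA here is two-class")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 3:
        raise AnalysisError("need >= 3 samples per class")
    if X.shape[0] <= n_components:
        raise AnalysisError("need more samples than components")
    y = (labels == classes[1]).astype(float)

    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    W, P, q, T = _nipals_pls1(xc, yc, n_components)
    tss = float(yc @ yc)
    y_hat = T @ q
    r2y = float(1.0 - ((yc - y_hat) @ (yc - y_hat)) / tss) if tss > 0 else 0.0

    # VIP: importance of feature j aggregated over components, weighted by
    # each component's share of explained label variance
    ss_comp = q ** 2 * np.einsum("ia,ia->a", T, T)
    denom = ss_comp.sum()
    p_feat = X.shape[1]
    if denom > 0 and W.shape[1] > 0:
        wnorm2 = (W ** 2) / (W ** 2).sum(axis=0, keepdims=True)
        vip = np.sqrt(p_feat * (wnorm2 @ ss_comp) / denom)
    else:
        vip = np.ones(p_feat)

    press = 0.0
    n = X.shape[0]
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xtr, ytr = X[mask], y[mask]
        mu_x, mu_y = Xtr.mean(axis=0), ytr.mean()
        Wf, Pf, qf, _ = _nipals_pls1(Xtr - mu_x, ytr - mu_y, n_components)
        beta = _pls_coefficients(Wf, Pf, qf)
        pred = mu_y + (X[i] - mu_x) @ beta
        press += (y[i] - pred) ** 2
    q2 = float(1.0 - press / tss) if tss > 0 else 0.0

    return PlsModel(n_components=W.shape[1], x_weights=W, x_loadings=P,
                    y_loadings=q, x_scores=T, r2y=r2y, q2=q2,
                    vip=pd.Series(vip, index=values.columns),
                    classes=classes,
                    feature_keys=list(values.columns))


# ---------------------------------------------------------------------------
# PCA / HCA
# ---------------------------------------------------------------------------

def pca_scores(
    tm: TransformedMatrix | pd.DataFrame,
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal-component scores and explained-variance fractions."""
    values = tm.values if isinstance(tm, TransformedMatrix) else tm
    X = np.asarray(values, dtype=float)
    if X.shape[0] < 2:
        raise AnalysisError("PCA needs >= 2 samples")
    xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    total = float((s ** 2).sum())
    explained = (s ** 2) / total if total > 0 else np.zeros_like(s)
    k = min(n_components, s.size)
    scores = u[:, :k] * s[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    return (pd.DataFrame(scores, index=values.index, columns=cols),
            explained[:k])


@dataclass
class HcaResult:
    linkage_matrix: np.ndarray
    leaf_order: list[int]
    labels: list[str]

    def to_newick(self) -> str:
        """Dendrogram in Newick format with merge heights as branch lengths."""
        if len(self.labels) == 1:
            return f"{self.labels[0]};"
        tree = to_tree(self.linkage_matrix)

        def recurse(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return f"({recurse(tree.left, tree.dist)},{recurse(tree.right, tree.dist)});"


def hca(
    tm: TransformedMatrix | pd.DataFrame,
    metric: str = "euclidean",
    method: str = "ward",
    labels: Sequence[str] | None = None,
) -> HcaResult:
    """Agglomerative clustering of samples (Ward linkage by default)."""
    values = tm.values if isinstance(tm, TransformedMatrix) else tm
    X = np.asarray(values, dtype=float)
    if labels is None:
        labels = [str(i) for i in values.index]
    if X.shape[0] < 2:
        return HcaResult(np.empty((0, 4)), [0], list(labels))
    Z = linkage(X, method=method, metric=metric)
    return HcaResult(Z, [int(i) for i in leaves_list(Z)], list(labels))


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk normality test (W statistic, p-value)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise AnalysisError("Shapiro-Wilk needs n >= 3")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)
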