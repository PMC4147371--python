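"""Publication-style figures for the standard pipeline outputs."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .stats_suite import RocResult, VolcanoRow  # noqa: E402


def volcano_plot(rows: Sequence[VolcanoRow], path: str | Path,
                 fc_thresh: float = 1.5, p_thresh: float = 0.05) -> Path:
    """Log2 fold change vs -log10 p, significant features highlighted."""
    fc = np.array([r.fold_change for r in rows])
    p = np.array([max(r.p_paired, 1e-300) for r in rows])
    sig = np.array([r.significant for r in rows])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.log2(fc[~sig]), -np.log10(p[~sig]), s=12, c="grey",
               alpha=0.6, label="n.s.")
    if sig.any():
        ax.scatter(np.log2(fc[sig]), -np.log10(p[sig]), s=16, c="crimson",
                   label="significant")
    for x in (np.log2(fc_thresh), -np.log2(fc_thresh)):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.axhline(-np.log10(p_thresh), ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p (paired t-test)")
    ax.legend(frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def pca_plot(scores, groups: Sequence, explained: Sequence[float],
             path: str | Path) -> Path:
    """2D PCA scores colored by group (QCs cluster tightly when precision
    is good)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        ax.scatter(scores.iloc[sel.nonzero()[0], 0],
                   scores.iloc[sel.nonzero()[0], 1], s=18, label=str(g))
    ax.set_xlabel(f"PC1 ({explained[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({explained[1] * 100:.1f}%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def roc_plot(cases, controls, result: RocResult, path: str | Path) -> Path:
    """Empirical ROC curve for one marker with its AUC annotated."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    thresholds = np.unique(np.concatenate([cases, controls]))[::-1]
    tpr = [(cases >= th).mean() for th in thresholds]
    fpr = [(controls >= th).mean() for th in thresholds]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot([0] + fpr + [1], [0] + tpr + [1], drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", lw=0.8, c="grey")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{result.label} AUC = {result.auc:.3f}", fontsize=10)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
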