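"""OGTT glucose-curve analytics and cohort-level arithmetic.

The three glucose-homeostasis endpoints of an oral glucose tolerance test
are fasting glucose (FG, 0 min), 2-h post-load glucose (2hPG, 120 min) and
the total area under the glucose curve (tAUC, trapezoidal rule over
0-120 min, in mM*min).  Cohort helpers compute within-subject change
statistics, the paired t-test, the two-sided Grubbs outlier test, and the
responder taxonomy on the change in 2hPG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study_design import SubjectRecord, records_to_frame

DELTA_COLUMNS = ("d_vo2max", "d_wmax", "d_fg", "d_p2hg", "d_tauc")


class IncompleteCurveError(ValueError):
    """Curve lacks the anchor timepoints (0 and end-of-test)."""


class DegenerateInputError(ValueError):
    """A statistic is undefined on this input (e.g. zero variance)."""


@dataclass
class OGTTCurve:
    """One glucose tolerance test: times (min, from 0) and glucose (mM)."""

    times: np.ndarray
    glucose: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if self.times.size != self.glucose.size or self.times.size < 2:
            raise ValueError("need >= 2 (time, glucose) pairs of equal length")
        if self.times[0] != 0:
            raise ValueError("curve must start at 0 min")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(self.glucose > 0):
            raise ValueError("glucose values must be positive")


class GlucoseMetrics(NamedTuple):
    fg: float      # mM at 0 min
    p2hg: float    # mM at 120 min
    tauc: float    # mM*min, trapezoidal 0-120 min


class OutlierResult(NamedTuple):
    statistic_g: float
    critical_g: float
    flagged_index: int | None
    alpha: float


class PairedTResult(NamedTuple):
    t: float
    p: float
    df: int


@dataclass(frozen=True)
class ResponderCall:
    subject_id: str
    delta_p2hg: float
    call: str  # positive | non_responder | negative


def compute_metrics(curve: OGTTCurve, end_min: float = 120.0) -> GlucoseMetrics:
    """FG, 2hPG and trapezoidal tAUC from one OGTT curve.

    Requires samples at exactly 0 and ``end_min`` minutes.
    """
    t, g = curve.times, curve.glucose
    if end_min not in t:
        raise IncompleteCurveError(f"curve lacks a {end_min:g}-min sample")
    mask = t <= end_min
    tw, gw = t[mask], g[mask]
    tauc = float(np.sum((gw[:-1] + gw[1:]) / 2.0 * np.diff(tw)))
    return GlucoseMetrics(fg=float(g[0]),
                          p2hg=float(g[t == end_min][0]),
                          tauc=tauc)


def cohort_deltas(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Mean and sample SD (n-1) of each within-subject change column."""
    if len(records) < 2:
        raise ValueError("need at least two subjects")
    df = records_to_frame(records)[list(DELTA_COLUMNS)]
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1),
                         "n": df.count()})


def paired_t_test(deltas: Sequence[float]) -> PairedTResult:
    """One-sample t-test of paired differences against zero (two-tailed)."""
    x = np.asarray(deltas, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need n >= 2 differences")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance in differences")
    n = x.size
    t = x.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), float(p), n - 1)


def grubbs_test(values: Sequence[float], alpha: float = 0.05) -> OutlierResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x - mean|/s is compared against the standard critical value
    built from the t-distribution at significance ``alpha``; the extreme
    observation is flagged only when G exceeds it.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateInputError("Grubbs test needs n >= 3")
    s = x.std(ddof=1)
    if s == 0:
        raise DegenerateInputError("zero variance")
    dev = np.abs(x - x.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / s)
    t_crit = stats.t.ppf(alpha / (2.0 * n), df=n - 2)
    g_crit = float((n - 1) / np.sqrt(n)
                   * np.sqrt(t_crit ** 2 / (n - 2 + t_crit ** 2)))
    return OutlierResult(g, g_crit, idx if g > g_crit else None, alpha)


def classify_responders(
    deltas_p2hg: pd.Series | dict[str, float],
    pos_thresh: float = -0.5,
    neg_thresh: float = 0.5,
) -> tuple[list[ResponderCall], dict[str, int]]:
    """Partition subjects by their change in 2hPG after intervention.

    positive: delta <= ``pos_thresh`` (improved glucose tolerance);
    negative: delta >= ``neg_thresh`` (worsened); non_responder otherwise.
    """
    series = pd.Series(deltas_p2hg, dtype=float)
    calls = []
    for subj, d in series.items():
        if d <= pos_thresh:
            call = "positive"
        elif d >= neg_thresh:
            call = "negative"
        else:
            call = "non_responder"
        calls.append(ResponderCall(str(subj), float(d), call))
    counts = {"positive": 0, "non_responder": 0, "negative": 0}
    for c in calls:
        counts[c.call] += 1
    return calls, counts


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two equal-length samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance input")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def curves_to_frame(curves: dict[tuple[str, str], OGTTCurve]) -> pd.DataFrame:
    rows = []
    for (subj, state), curve in sorted(curves.items()):
        for t, g in zip(curve.times, curve.glucose):
            rows.append({"subject": subj, "state": state,
                         "time_min": float(t), "glucose_mM": float(g)})
    return pd.DataFrame(rows)


def frame_to_curves(df: pd.DataFrame) -> dict[tuple[str, str], OGTTCurve]:
    curves = {}
    for (subj, state), grp in df.groupby(["subject", "state"]):
        grp = grp.sort_values("time_min")
        curves[(str(subj), str(state))] = OGTTCurve(
            grp["time_min"].to_numpy(), grp["glucose_mM"].to_numpy())
    return curves
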