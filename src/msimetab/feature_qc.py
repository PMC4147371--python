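"""Two-stage feature curation for the multiplexed CE-MS workflow.

Stage one is the dilution trend filter, an untargeted primary screen run on
serially diluted pooled plasma: a feature is authentic only if it is
reproducible (replicate CV < 40%), linear with dilution (R^2 > 0.90 over at
least three detected levels) and silent in the blank.  Stage two is the
study-level filter: a curated feature enters the final data matrix only if
detected in at least 75% of study samples with acceptable precision
(CV < 40%) across the pooled QCs injected in every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

META_COLUMNS = ["subject", "timepoint", "state", "is_qc", "run_id"]


class InputError(ValueError):
    pass


@dataclass
class DilutionSeries:
    """Replicate responses of one feature across a dilution ladder.

    ``levels`` are dilution factors (1 = undiluted pooled sample,
    0 = blank); ``responses`` is levels x replicates with NaN marking
    non-detection.
    """

    metabolite_key: str
    levels: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2 or \
                self.responses.shape[0] != self.levels.size:
            raise InputError("responses must be (n_levels, n_replicates)")
        if self.responses.shape[1] < 1:
            raise InputError("need at least one replicate")
        if 0.0 not in self.levels:
            raise InputError("dilution series must include a blank (level 0)")


@dataclass(frozen=True)
class FilterVerdict:
    metabolite_key: str
    kept: bool
    reason: str  # pass | blank | levels | precision | linearity
    cv: float | None = None
    r2_linearity: float | None = None
    n_levels_detected: int = 0
    blank_detected: bool = False


@dataclass(frozen=True)
class StudyFilterVerdict:
    metabolite_key: str
    kept: bool
    reason: str  # pass | detection | qc_precision
    detect_frac: float
    qc_cv: float


@dataclass
class QcReport:
    per_feature_cv: pd.Series
    mean_cv: float
    missing_frac: pd.Series


@dataclass
class FeatureMatrix:
    """Samples x features table with sample metadata alongside.

    ``meta`` has columns ``subject, timepoint, state, is_qc, run_id``;
    ``values`` shares its index and has one column per m/z:RMT feature key.
    Missing cells mean the feature was not detected in that sample.
    """

    meta: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise InputError(f"meta lacks columns {missing}")
        if not self.meta.index.equals(self.values.index):
            raise InputError("meta and values must share an index")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate feature keys")

    @property
    def qc_mask(self) -> pd.Series:
        return self.meta["is_qc"].astype(bool)

    @property
    def feature_keys(self) -> list[str]:
        return list(self.values.columns)

    def study_values(self) -> pd.DataFrame:
        return self.values.loc[~self.qc_mask]

    def qc_values(self) -> pd.DataFrame:
        return self.values.loc[self.qc_mask]

    def subset(self, keys: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.meta.copy(), self.values[list(keys)].copy())

    def to_csv(self, path: str | Path) -> None:
        pd.concat([self.meta, self.values], axis=1).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"{Path(path).name}: missing columns {missing}")
        feature_cols = [c for c in df.columns if c not in META_COLUMNS]
        return cls(df[META_COLUMNS], df[feature_cols])


def dilution_trend_filter(
    series: DilutionSeries,
    cv_max: float = 0.40,
    r2_min: float = 0.90,
    min_levels: int = 3,
) -> FilterVerdict:
    """Primary untargeted screen on a pooled-sample dilution ladder.

    Criteria, checked in order (the reason names the first failure):
    no blank signal; >= ``min_levels`` detected non-blank levels; replicate
    CV at the undiluted level strictly below ``cv_max``; linearity R^2 of
    mean response vs dilution factor above ``r2_min``.
    """
    lv, resp = series.levels, series.responses
    blank_detected = bool(np.isfinite(resp[lv == 0]).any())

    nonblank = lv > 0
    detected_levels = np.isfinite(resp[nonblank]).any(axis=1)
    n_detected = int(detected_levels.sum())

    undil = resp[lv == np.max(lv)]
    undil = undil[np.isfinite(undil)]
    cv = None
    if undil.size >= 1 and undil.mean() != 0:
        cv = float(undil.std(ddof=1) / undil.mean()) if undil.size > 1 else 0.0

    r2 = None
    if n_detected >= 2:
        x = lv[nonblank][detected_levels]
        y = np.nanmean(resp[nonblank][detected_levels], axis=1)
        if np.std(y) == 0:
            r2 = 0.0
        else:
            fit = stats.linregress(x, y)
            r2 = float(fit.rvalue ** 2)

    if blank_detected:
        reason = "blank"
    elif n_detected < min_levels:
        reason = "levels"
    elif cv is None or cv >= cv_max:
        reason = "precision"
    elif r2 is None or r2 <= r2_min:
        reason = "linearity"
    else:
        reason = "pass"
    return FilterVerdict(series.metabolite_key, kept=(reason == "pass"),
                         reason=reason, cv=cv, r2_linearity=r2,
                         n_levels_detected=n_detected,
                         blank_detected=blank_detected)


def study_filter(
    matrix: FeatureMatrix,
    min_detect_frac: float = 0.75,
    qc_cv_max: float = 0.40,
) -> tuple[FeatureMatrix, list[StudyFilterVerdict]]:
    """Retain features detected in >= 75% of study samples with QC CV < 40%.

    Detection fractions are computed over study (non-QC) samples; precision
    is the CV across the pooled-QC rows.
    """
    if not matrix.qc_mask.any():
        raise InputError("matrix has no QC rows")
    study = matrix.study_values()
    qc = matrix.qc_values()
    verdicts = []
    kept_keys = []
    for key in matrix.feature_keys:
        frac = float(study[key].notna().mean())
        vals = qc[key].dropna()
        if len(vals) >= 2 and vals.mean() != 0:
            cv = float(vals.std(ddof=1) / vals.mean())
        elif len(vals) == 1:
            cv = 0.0
        else:
            cv = float("inf")
        if frac < min_detect_frac:
            reason = "detection"
        elif not cv < qc_cv_max:
            reason = "qc_precision"
        else:
            reason = "pass"
            kept_keys.append(key)
        verdicts.append(StudyFilterVerdict(key, reason == "pass", reason,
                                           frac, cv))
    return matrix.subset(kept_keys), verdicts


def qc_monitor(matrix: FeatureMatrix) -> QcReport:
    """Per-feature CV across pooled-QC injections, plus the overall mean.

    The mean CV across retained features is the study's headline analytical
    precision figure.
    """
    qc = matrix.qc_values()
    if len(qc) < 2:
        raise InputError("need at least two QC rows")
    mean = qc.mean()
    sd = qc.std(ddof=1)
    cv = (sd / mean).replace([np.inf, -np.inf], np.nan)
    return QcReport(per_feature_cv=cv,
                    mean_cv=float(cv.dropna().mean()),
                    missing_frac=qc.isna().mean())


def verdicts_to_frame(verdicts: Sequence) -> pd.DataFrame:
    return pd.DataFrame([v.__dict__ for v in verdicts])


def build_feature_matrix(
    keyed_table: pd.DataFrame,
    segment_samples: dict[tuple[str, int], dict],
) -> FeatureMatrix:
    """Assemble a keyed assigned-peak table into a samples x features matrix.

    ``keyed_table`` is the concatenated per-run peak table with a ``key``
    column (see ``processing.assign_feature_keys``); ``segment_samples``
    maps (run_id, segment) to sample metadata dicts with the
    ``subject,timepoint,state,is_qc,run_id`` fields.
    """
    table = keyed_table

    meta_rows = []
    index = []
    for (rid, seg), info in sorted(segment_samples.items()):
        index.append((rid, seg))
        meta_rows.append({k: info.get(k) for k in META_COLUMNS})
    meta = pd.DataFrame(meta_rows,
                        index=pd.MultiIndex.from_tuples(
                            index, names=["run_id_idx", "segment"]))

    values = pd.DataFrame(index=meta.index,
                          columns=sorted(set(table["key"])), dtype=float)
    for row in table.itertuples():
        idx = (row.run_id, row.segment)
        if idx in values.index:
            values.loc[idx, row.key] = row.rpa
    meta = meta.reset_index(drop=True)
    values = values.reset_index(drop=True)
    return FeatureMatrix(meta, values)
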