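"""Repeated-measures/cross-over study design mapped onto multiplexed CE-MS runs.

The study layout is a factorial design: each subject completes an oral
glucose tolerance test (OGTT, blood draws at six timepoints over 2 h) in two
training states (naive = before exercise intervention, trained = after).
Samples are analyzed by multi-segment injection CE-MS, where one run carries
seven serially injected plugs: six study samples plus one pooled quality
control (QC) in the seventh segment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Sequence

import pandas as pd

DEFAULT_TIMEPOINTS = (0, 20, 30, 60, 90, 120)
STATES = ("naive", "trained")
SAMPLES_PER_RUN = 6  # segment 7 is reserved for the pooled QC
QC_SEGMENT = 7

COHORT_COLUMNS = [
    "subject_id", "age", "bmi", "pct_fat",
    "vo2max", "d_vo2max", "wmax", "d_wmax",
    "fg", "d_fg", "p2hg", "d_p2hg", "tauc", "d_tauc",
]


class InvalidDesignError(ValueError):
    """Raised when a study design cannot be mapped onto 7-segment runs."""


class FixtureParseError(ValueError):
    """Raised when the packaged cohort table cannot be parsed."""


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's anthropometrics, fitness and glucose endpoints.

    Deltas (``d_*``) are trained-minus-naive changes; the plain columns are
    the naive-state (baseline) values.  Units: age in years, bmi in kg/m^2,
    pct_fat in percent, vo2max in mL/kg/min, wmax in W, fg and p2hg in mM,
    tauc in mM*min over the 0-120 min OGTT.
    """

    subject_id: str
    age: float
    bmi: float
    pct_fat: float
    vo2max: float
    d_vo2max: float
    wmax: float
    d_wmax: float
    fg: float
    d_fg: float
    p2hg: float
    d_p2hg: float
    tauc: float
    d_tauc: float

    def __post_init__(self) -> None:
        if self.bmi <= 0:
            raise ValueError(f"{self.subject_id}: bmi must be positive")
        for name in ("fg", "p2hg", "tauc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.subject_id}: {name} must be >= 0")


@dataclass(frozen=True)
class SampleMeta:
    """Placement of one sample (study sample, QC or blank) in a run."""

    subject_id: str | None
    timepoint: int | None
    training_state: str | None
    is_qc: bool
    run_id: str
    segment_index: int

    @property
    def is_blank(self) -> bool:
        return self.subject_id is None and not self.is_qc


@dataclass
class StudyManifest:
    """Full sample-to-run mapping with one QC per run.

    ``samples`` lists study samples only; QCs are in ``qcs`` and padding
    blanks (for designs not divisible by 6) in ``blanks``.
    """

    subjects: list[str]
    timepoints: tuple[int, ...]
    states: tuple[str, ...]
    samples: list[SampleMeta]
    qcs: list[SampleMeta]
    blanks: list[SampleMeta] = field(default_factory=list)

    @property
    def run_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.run_id, None)
        return list(seen)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    def segments(self, run_id: str) -> list[SampleMeta]:
        """Ordered 7-segment content of one run (samples, blanks, QC)."""
        members = [s for s in self.samples + self.blanks + self.qcs
                   if s.run_id == run_id]
        return sorted(members, key=lambda s: s.segment_index)

    def to_json(self) -> str:
        payload = {
            "timepoints": list(self.timepoints),
            "states": list(self.states),
            "runs": {
                rid: [asdict(s) for s in self.segments(rid)]
                for rid in self.run_ids
            },
        }
        return json.dumps(payload, indent=1)


def build_manifest(
    n_subjects: int,
    timepoints: Sequence[int] = DEFAULT_TIMEPOINTS,
    states: Sequence[str] = STATES,
) -> StudyManifest:
    """Lay out ``n_subjects x timepoints x states`` samples onto 7-segment runs.

    Ordering is deterministic: subject-major, state next (naive before
    trained, i.e. the order given), timepoint-minor.  Runs carry six study
    samples in segments 1-6 and the pooled QC in segment 7; a final partial
    run is padded with blanks, which are recorded on the manifest.
    """
    if n_subjects < 1:
        raise InvalidDesignError("need at least one subject")
    if not timepoints:
        raise InvalidDesignError("timepoints must be non-empty")
    if not states:
        raise InvalidDesignError("states must be non-empty")
    tps = tuple(int(t) for t in timepoints)
    if any(b <= a for a, b in zip(tps, tps[1:])):
        raise InvalidDesignError("timepoints must be strictly increasing")

    subjects = [f"S{i}" for i in range(1, n_subjects + 1)]
    ordered = [
        (subj, state, tp)
        for subj in subjects
        for state in states
        for tp in tps
    ]

    n_runs = math.ceil(len(ordered) / SAMPLES_PER_RUN)
    samples: list[SampleMeta] = []
    qcs: list[SampleMeta] = []
    blanks: list[SampleMeta] = []
    for r in range(n_runs):
        run_id = f"run{r + 1:03d}"
        chunk = ordered[r * SAMPLES_PER_RUN:(r + 1) * SAMPLES_PER_RUN]
        for seg, (subj, state, tp) in enumerate(chunk, start=1):
            samples.append(SampleMeta(subj, tp, state, False, run_id, seg))
        for seg in range(len(chunk) + 1, SAMPLES_PER_RUN + 1):
            blanks.append(SampleMeta(None, None, None, False, run_id, seg))
        qcs.append(SampleMeta(None, None, None, True, run_id, QC_SEGMENT))

    return StudyManifest(
        subjects=subjects,
        timepoints=tps,
        states=tuple(states),
        samples=samples,
        qcs=qcs,
        blanks=blanks,
    )


def load_cohort_table() -> list[SubjectRecord]:
    """Load the packaged 11-subject cohort table.

    The CSV ships with the package (``data/cohort_endpoints.csv``); bracketed
    trained-minus-naive changes from the source table are stored in the
    ``d_*`` columns.
    """
    ref = resources.files("msimetab.data").joinpath("cohort_endpoints.csv")
    with ref.open("r") as fh:
        return parse_cohort_table(fh)


def parse_cohort_table(handle) -> list[SubjectRecord]:
    """Parse a cohort CSV with the packaged cohort column layout."""
    try:
        df = pd.read_csv(handle)
    except pd.errors.EmptyDataError as exc:
        raise FixtureParseError("cohort table is empty") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise FixtureParseError(f"cohort table missing columns: {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(SubjectRecord(
                subject_id=str(row["subject_id"]),
                **{c: float(row[c]) for c in COHORT_COLUMNS[1:]},
            ))
        except (TypeError, ValueError) as exc:
            raise FixtureParseError(
                f"cohort table row {i} ({row.get('subject_id', '?')}): {exc}"
            ) from exc
    return records


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabular view of subject records, indexed by subject_id."""
    df = pd.DataFrame([asdict(r) for r in records])
    return df.set_index("subject_id")
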