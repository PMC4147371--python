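"""Synthetic cohort and raw-signal generator for multiplexed CE-MS metabolomics.

Generates, from a seed, (a) ground-truth plasma metabolite responses for a
repeated-measures OGTT x training-state design, (b) per-subject glucose
curves with a planted linear relation between baseline metabolites and the
training-induced change in 2-h post-load glucose, and (c) raw multiplexed
electropherograms in which every metabolite appears as up to seven
time-ordered Gaussian peaks (one per injected sample plug, the seventh being
a pooled QC).

Effect structure emulated: amino-acid-like metabolites decline over the 2-h
post-glucose time course; disulfide-like metabolites decline with training;
a pooled QC repeats with a configurable analytical coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .glucose import OGTTCurve
from .study_design import StudyManifest, QC_SEGMENT, SAMPLES_PER_RUN
from .traces import RawTrace

# Internal standard: 3-chloro-L-tyrosine (Cl-Tyr), 25 uM in every plug,
# detected as [M+H]+.
IS_NAME = "Cl-Tyr"
IS_MZ = 216.042

REDUNDANCY_OFFSETS = {
    "isotope": 1.00336,        # 13C
    "sodium_adduct": 21.98194,  # Na - H
    "nh3_loss": -17.02655,
    "water_loss": -18.01056,
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


class RunCapacityError(ValueError):
    """More samples than the seven-segment format can carry."""


# ---------------------------------------------------------------------------
# Injection program
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InjectionSegment:
    kind: str  # "sample" or "spacer"
    duration_s: float
    pressure_mbar: float = 100.0

    def __post_init__(self) -> None:
        if self.kind not in ("sample", "spacer"):
            raise ConfigError(f"unknown segment kind {self.kind!r}")
        if self.duration_s <= 0:
            raise ConfigError("segment durations must be positive")


@dataclass(frozen=True)
class InjectionProgram:
    """Ordered hydrodynamic injection sequence of sample and spacer plugs."""

    segments: tuple[InjectionSegment, ...]

    def __post_init__(self) -> None:
        if any(not isinstance(s, InjectionSegment) for s in self.segments):
            raise ConfigError("segments must be InjectionSegment instances")

    @property
    def n_samples(self) -> int:
        return sum(1 for s in self.segments if s.kind == "sample")


class InjectionTiming(NamedTuple):
    total_s: float
    plug_fraction: float


def default_injection_program() -> InjectionProgram:
    """Seven 5-s sample plugs alternating with BGE spacers at 100 mbar.

    Six 40-s spacers separate the first six samples; the seventh sample is
    followed by a short 5-s spacer, for a 280-s total injection.
    """
    segments: list[InjectionSegment] = []
    for i in range(7):
        segments.append(InjectionSegment("sample", 5.0))
        segments.append(InjectionSegment("spacer", 40.0 if i < 6 else 5.0))
    return InjectionProgram(tuple(segments))


def total_injection_time(program: InjectionProgram) -> InjectionTiming:
    """Total injection time and the equivalent capillary plug fraction.

    The reference program (280 s) fills about 30% of the capillary; the
    fraction scales linearly with injection time.
    """
    total = float(sum(s.duration_s for s in program.segments))
    return InjectionTiming(total, total / 280.0 * 0.30)


# ---------------------------------------------------------------------------
# Metabolite panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaboliteSpec:
    """Ground-truth description of one plasma feature.

    ``time_effect`` is the fractional change at 120 min relative to 0 min
    (-0.4 means a 40% post-prandial decrease); ``training_effect`` is the
    fractional trained-vs-naive change.  ``dilution_behavior`` controls how
    the feature behaves in a dilution-series run: "authentic" scales with
    dilution and is silent in the blank, "blank_contaminant" appears in
    every segment including the blank, "nonlinear" gives a flat,
    dilution-independent response.
    """

    name: str
    mz: float
    rmt_true: float
    base_conc: float
    time_effect: float = 0.0
    training_effect: float = 0.0
    cv_biological: float = 0.20
    is_redundant_of: str | None = None
    redundancy_kind: str = "none"
    redundancy_frac: float = 0.0
    dilution_behavior: str = "authentic"

    def __post_init__(self) -> None:
        if self.mz <= 0 or self.rmt_true <= 0:
            raise ConfigError(f"{self.name}: mz and rmt_true must be positive")
        if self.base_conc < 0:
            raise ConfigError(f"{self.name}: base_conc must be >= 0")
        if not (abs(self.time_effect) < 1 and abs(self.training_effect) < 1):
            raise ConfigError(f"{self.name}: effects must be in (-1, 1)")
        if self.redundancy_kind not in ("none", *REDUNDANCY_OFFSETS):
            raise ConfigError(
                f"{self.name}: unknown redundancy kind {self.redundancy_kind}")

    @property
    def key(self) -> str:
        return f"{self.mz:.3f}:{self.rmt_true:.3f}"


# Named metabolites with the effect classes observed in plasma OGTT studies:
# branched-chain/aromatic/sulfur amino acids and urea-cycle/carnitine
# intermediates fall after glucose loading; oxidized disulfides fall with
# training; ornithine responds to both.
_NAMED_PANEL: list[tuple] = [
    # name, mz, rmt, base_conc, time_effect, training_effect
    ("Leu", 132.102, 0.843, 5.0, -0.40, 0.0),
    ("Ile", 132.102, 0.832, 2.5, -0.32, 0.0),
    ("Val", 118.086, 0.818, 6.0, -0.28, 0.0),
    ("Phe", 166.086, 0.918, 2.2, -0.30, 0.0),
    ("Trp", 205.097, 0.917, 1.8, -0.22, 0.0),
    ("Tyr", 182.081, 0.951, 2.0, -0.20, 0.0),
    ("Met", 150.058, 0.889, 1.2, -0.30, 0.0),
    ("Cit", 176.103, 0.930, 1.4, -0.33, 0.0),
    ("Lys", 147.113, 0.562, 4.5, -0.20, 0.0),
    ("His", 156.077, 0.606, 2.8, -0.15, 0.0),
    ("Arg", 175.119, 0.579, 3.0, -0.15, 0.0),
    ("Asp", 134.045, 1.333, 1.0, -0.15, 0.0),
    ("C0", 162.112, 0.720, 1.6, -0.05, 0.0),
    ("C2", 204.123, 0.735, 1.1, -0.30, 0.0),
    ("TML", 189.160, 0.586, 1.0, +0.18, +0.10),
    ("Orn", 133.097, 0.567, 1.8, -0.18, +0.20),
    ("Cys-SS", 241.031, 0.935, 2.4, 0.0, -0.22),
    ("GlyCys-Cys-SS", 298.053, 0.788, 1.3, 0.0, -0.25),
    ("GSH-Cys-SS", 427.095, 0.997, 1.1, 0.0, -0.25),
    ("PrBt", 144.102, 0.970, 1.5, 0.0, +0.15),
]


def default_panel(n_features: int = 55) -> list[MetaboliteSpec]:
    """The default authentic plasma panel: 20 named + filler features.

    Filler features ("U21", "U22", ...) carry no planted effect and stand in
    for the unidentified m/z:RMT features of a real plasma screen; their
    masses and migration times are laid out deterministically.
    """
    specs = [
        MetaboliteSpec(name, mz, rmt, conc, te, tre)
        for name, mz, rmt, conc, te, tre in _NAMED_PANEL
    ]
    n_fill = max(0, n_features - len(specs))
    for i in range(n_fill):
        mz = 90.0 + 5.37 * i  # deterministic spread, avoids named masses
        rmt = 0.52 + (i * 0.761) % 0.78
        specs.append(MetaboliteSpec(f"U{len(_NAMED_PANEL) + i + 1}",
                                    round(mz, 3), round(rmt, 3),
                                    base_conc=1.0 + (i % 7) * 0.8))
    return specs[:n_features]


def make_feature_universe(
    panel: Sequence[MetaboliteSpec] | None = None,
    n_blank_contaminants: int = 8,
    n_nonlinear: int = 8,
    redundant_of: Sequence[tuple[str, str]] = (
        ("Leu", "isotope"), ("Phe", "sodium_adduct"), ("Lys", "nh3_loss"),
    ),
) -> list[MetaboliteSpec]:
    """Authentic panel plus planted noise: blank contaminants, flat junk
    features and redundant satellite ions (isotopes, adducts, losses).

    The two-stage feature curation should reject everything but the
    authentic panel.
    """
    panel = list(default_panel() if panel is None else panel)
    by_name = {s.name: s for s in panel}
    universe = list(panel)
    for i in range(n_blank_contaminants):
        universe.append(MetaboliteSpec(
            f"BLK{i + 1}", round(300.0 + 3.17 * i, 3),
            round(0.55 + (i * 0.119) % 0.7, 3), base_conc=1.2,
            dilution_behavior="blank_contaminant"))
    for i in range(n_nonlinear):
        universe.append(MetaboliteSpec(
            f"JUNK{i + 1}", round(350.0 + 2.71 * i, 3),
            round(0.60 + (i * 0.173) % 0.65, 3), base_conc=1.5,
            dilution_behavior="nonlinear"))
    for parent_name, kind in redundant_of:
        parent = by_name[parent_name]
        universe.append(MetaboliteSpec(
            f"{parent_name}+{kind}",
            round(parent.mz + REDUNDANCY_OFFSETS[kind], 5),
            parent.rmt_true, parent.base_conc,
            parent.time_effect, parent.training_effect,
            is_redundant_of=parent_name, redundancy_kind=kind,
            redundancy_frac=0.25))
    return universe


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseConfig:
    """Coefficient-of-variation targets for the generative model.

    ``cv_analytical`` drives both per-measurement multiplicative noise and
    QC replicate scatter; ``cv_biological_default`` is used for specs that
    do not set their own biological CV.
    """

    cv_analytical: float = 0.14
    cv_biological_default: float = 0.20

    def __post_init__(self) -> None:
        if self.cv_analytical <= 0 or self.cv_biological_default <= 0:
            raise ConfigError("CVs must be positive")


@dataclass(frozen=True)
class PlantedGlucoseModel:
    """Known linear link from baseline metabolites to the change in 2hPG.

    Each predictor is (metabolite name, kind) with kind one of "0min"
    (log10 response at 0 min, naive state), "120min", or "ratio120_0"
    (log10 of the 120/0 min response ratio).  Predictors are standardized
    across subjects before the betas apply, so betas are in mM per SD.
    """

    predictors: tuple[tuple[str, str], ...] = (
        ("Orn", "0min"), ("Leu", "ratio120_0"), ("Cys-SS", "0min"))
    betas: tuple[float, ...] = (0.8, 0.6, -0.5)
    intercept: float = -0.3
    noise_sd: float = 0.10

    def __post_init__(self) -> None:
        if len(self.predictors) != len(self.betas):
            raise ConfigError("one beta per predictor required")


@dataclass
class CohortTruth:
    """Everything the generator knows: specs, responses, curves, seed."""

    specs: list[MetaboliteSpec]
    concentrations: pd.DataFrame  # subject, timepoint, state, metabolite, response
    qc_responses: pd.DataFrame    # run_id, metabolite, response
    glucose_curves: dict[tuple[str, str], OGTTCurve]
    planted: PlantedGlucoseModel
    planted_d_p2hg: pd.Series     # per-subject planted change in 2hPG (mM)
    seed: int

    def response_pivot(self) -> pd.DataFrame:
        """Wide samples x metabolites view of the study responses."""
        return self.concentrations.pivot_table(
            index=["subject", "timepoint", "state"],
            columns="metabolite", values="response")

    def glucose_frame(self) -> pd.DataFrame:
        rows = []
        for (subj, state), curve in sorted(self.glucose_curves.items()):
            for t, g in zip(curve.times, curve.glucose):
                rows.append({"subject": subj, "state": state,
                             "time_min": t, "glucose_mM": g})
        return pd.DataFrame(rows)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-one multiplicative lognormal noise with the given CV."""
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _time_multiplier(t: float, t_max: float, effect: float) -> float:
    # linear (hence monotone) interpolation between the 0-min multiplier (1)
    # and the end-of-curve multiplier (1 + effect)
    return 1.0 + effect * (t / t_max)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _ogtt_curve(times: np.ndarray, fg: float, peak_t: float, peak_g: float,
                g_end: float) -> OGTTCurve:
    t = np.asarray(times, dtype=float)
    rise = fg + (peak_g - fg) * _smoothstep(t / peak_t)
    t_end = t[-1]
    relax = g_end + (peak_g - g_end) * _smoothstep(
        (t_end - t) / max(t_end - peak_t, 1.0))
    glucose = np.where(t <= peak_t, rise, relax)
    return OGTTCurve(times=t, glucose=np.maximum(glucose, 2.5))


def simulate_cohort(
    design: StudyManifest,
    panel: Sequence[MetaboliteSpec] | None = None,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    planted: PlantedGlucoseModel | None = None,
) -> CohortTruth:
    """Draw ground-truth responses and glucose curves for a study design.

    Response model per study sample:
    ``base_conc x subject effect x time trajectory x state multiplier x
    lognormal(analytical CV)``, where the subject effect is a mean-one
    lognormal with the metabolite's biological CV.  QC responses are the
    panel mean times lognormal(analytical CV), one draw per run.  The
    trained-state 2hPG of each subject's glucose curve carries a planted
    linear dependence on designated baseline predictors, enabling recovery
    of the prognostic model downstream.
    """
    panel = list(default_panel() if panel is None else panel)
    if not panel:
        raise ConfigError("panel must be non-empty")
    noise = noise or NoiseConfig()
    planted = planted or PlantedGlucoseModel()
    names = {s.name for s in panel if s.is_redundant_of is None}
    if any(met not in names for met, _ in planted.predictors):
        # reduced panels: remap the planted predictors onto what exists
        avail = sorted(names)
        k = min(len(planted.predictors), len(avail))
        planted = replace(
            planted,
            predictors=tuple((avail[i], planted.predictors[i][1])
                             for i in range(k)),
            betas=planted.betas[:k])
    rng = np.random.default_rng(seed)

    t_max = float(max(design.timepoints))
    primaries = [s for s in panel if s.is_redundant_of is None]

    # subject-level random effects, one per (subject, metabolite)
    subj_eff = {
        (subj, spec.name): _lognormal_factor(
            rng, spec.cv_biological or noise.cv_biological_default)
        for subj in design.subjects for spec in primaries
    }

    rows = []
    for subj in design.subjects:
        for state in design.states:
            trained = state != design.states[0]
            for tp in design.timepoints:
                for spec in primaries:
                    resp = (
                        spec.base_conc
                        * subj_eff[(subj, spec.name)]
                        * _time_multiplier(tp, t_max, spec.time_effect)
                        * (1.0 + spec.training_effect if trained else 1.0)
                        * _lognormal_factor(rng, noise.cv_analytical)
                    )
                    rows.append({"subject": subj, "timepoint": tp,
                                 "state": state, "metabolite": spec.name,
                                 "response": resp})
    conc = pd.DataFrame(rows)

    pooled = conc.groupby("metabolite")["response"].mean()
    qc_rows = []
    for rid in design.run_ids:
        for spec in primaries:
            qc_rows.append({
                "run_id": rid, "metabolite": spec.name,
                "response": pooled[spec.name]
                * _lognormal_factor(rng, noise.cv_analytical)})
    qc = pd.DataFrame(qc_rows)

    # planted prognostic structure: standardized baseline predictors -> d2hPG
    naive_state = design.states[0]
    pivot = conc.pivot_table(index=["subject", "timepoint", "state"],
                             columns="metabolite", values="response")
    X = np.zeros((len(design.subjects), len(planted.predictors)))
    for j, (met, kind) in enumerate(planted.predictors):
        for i, subj in enumerate(design.subjects):
            r0 = pivot.loc[(subj, design.timepoints[0], naive_state), met]
            r_end = pivot.loc[(subj, design.timepoints[-1], naive_state), met]
            if kind == "0min":
                X[i, j] = math.log10(r0)
            elif kind == "120min":
                X[i, j] = math.log10(r_end)
            elif kind == "ratio120_0":
                X[i, j] = math.log10(r_end / r0)
            else:
                raise ConfigError(f"unknown predictor kind {kind!r}")
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd = np.where(~np.isfinite(sd) | (sd == 0), 1.0, sd)  # n=1 degenerate
    Z = (X - mu) / sd
    d_p2hg = (planted.intercept + Z @ np.asarray(planted.betas)
              + rng.normal(0.0, planted.noise_sd, size=len(design.subjects)))
    d_series = pd.Series(d_p2hg, index=design.subjects, name="d_p2hg")

    times = np.asarray(design.timepoints, dtype=float)
    curves: dict[tuple[str, str], OGTTCurve] = {}
    for i, subj in enumerate(design.subjects):
        fg = float(np.clip(rng.normal(4.7, 0.7), 3.5, 6.5))
        peak_t = float(rng.choice([20.0, 30.0, 60.0]))
        peak_g = fg + float(np.clip(rng.normal(3.2, 0.8), 1.5, 5.0))
        g_end = float(np.clip(fg + rng.normal(0.5, 0.8), 3.0, 8.0))
        curves[(subj, naive_state)] = _ogtt_curve(times, fg, peak_t,
                                                  peak_g, g_end)
        if len(design.states) > 1:
            fg_tr = float(np.clip(fg + rng.normal(-0.1, 0.4), 3.0, 6.5))
            peak_tr = fg_tr + float(np.clip(rng.normal(3.0, 0.8), 1.5, 5.0))
            g_end_tr = max(g_end + float(d_p2hg[i]), 2.5)
            curves[(subj, design.states[1])] = _ogtt_curve(
                times, fg_tr, peak_t, peak_tr, g_end_tr)

    return CohortTruth(specs=panel, concentrations=conc, qc_responses=qc,
                       glucose_curves=curves, planted=planted,
                       planted_d_p2hg=d_series, seed=seed)


# ---------------------------------------------------------------------------
# Raw-trace synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakShapeConfig:
    """Signal-model parameters for raw-trace synthesis.

    The internal standard migrates at ``t_is_s`` in the first segment;
    successive plugs are offset by ``migration_offset_s`` so that seven
    peaks of one metabolite span roughly three minutes.  Analyte migration
    scales with its relative migration time, and peak area is
    ``response x is_area`` so that IS normalization recovers the response.
    """

    t_is_s: float = 1100.0
    migration_offset_s: float = 25.0
    sigma_s: float = 2.0
    baseline_sd: float = 100.0
    is_area: float = 2.0e4
    sample_hz: float = 2.0
    t_start_s: float = 400.0
    t_end_s: float = 1900.0
    drift: float = 1.0  # global migration-time multiplier (system drift)

    def __post_init__(self) -> None:
        if min(self.t_is_s, self.migration_offset_s, self.sigma_s,
               self.is_area, self.sample_hz) <= 0:
            raise ConfigError("peak-shape parameters must be positive")
        if self.baseline_sd < 0:
            raise ConfigError("baseline_sd must be >= 0")


def _add_gaussian(intens: np.ndarray, times: np.ndarray, apex: float,
                  area: float, sigma: float) -> None:
    height = area / (sigma * math.sqrt(2.0 * math.pi))
    intens += height * np.exp(-0.5 * ((times - apex) / sigma) ** 2)


def synthesize_run(
    run_id: str,
    segment_responses: dict[str, Sequence[float | None]],
    specs: Sequence[MetaboliteSpec],
    program: InjectionProgram | None = None,
    config: PeakShapeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RawTrace:
    """Render one multiplexed run as Gaussian peaks on ion channels.

    ``segment_responses`` maps metabolite name to a per-segment response
    sequence (``None`` = blank segment for that metabolite).  Each
    metabolite gets one channel at its m/z; redundant satellites get their
    own channel co-migrating with the parent.  The internal standard appears
    in every segment.  Passing ``rng`` adds Gaussian baseline noise of SD
    ``config.baseline_sd``; omit it for noise-free traces.
    """
    program = program or default_injection_program()
    config = config or PeakShapeConfig()
    n_slots = program.n_samples
    for name, responses in segment_responses.items():
        if len(responses) > n_slots:
            raise RunCapacityError(
                f"{name}: {len(responses)} samples exceed the "
                f"{n_slots}-segment format")

    by_name = {s.name: s for s in specs}
    times = np.arange(config.t_start_s, config.t_end_s,
                      1.0 / config.sample_hz)
    channels: dict[float, np.ndarray] = {}

    def channel_for(mz: float) -> np.ndarray:
        if mz not in channels:
            channels[mz] = np.zeros_like(times)
        return channels[mz]

    # internal standard in every segment
    is_intens = channel_for(IS_MZ)
    for k in range(n_slots):
        apex = config.drift * (config.t_is_s + k * config.migration_offset_s)
        _add_gaussian(is_intens, times, apex, config.is_area, config.sigma_s)

    for name, responses in segment_responses.items():
        spec = by_name[name]
        parent = by_name.get(spec.is_redundant_of or "", spec)
        intens = channel_for(spec.mz)
        for k, resp in enumerate(responses):
            if resp is None:
                continue
            area = resp * config.is_area
            if spec.is_redundant_of is not None:
                area *= spec.redundancy_frac
            # analyte co-migrates with its plug's IS, scaled by its RMT
            apex = config.drift * parent.rmt_true * (
                config.t_is_s + k * config.migration_offset_s)
            _add_gaussian(intens, times, apex, area, config.sigma_s)

    if rng is not None and config.baseline_sd > 0:
        for mz in channels:
            channels[mz] = np.maximum(
                channels[mz] + rng.normal(0, config.baseline_sd,
                                          size=times.size), 0.0)

    return RawTrace(run_id=run_id, times=times, channels=channels,
                    meta={"n_segments": n_slots,
                          "t_is_s": config.t_is_s,
                          "migration_offset_s": config.migration_offset_s})


def run_segment_responses(
    truth: CohortTruth, design: StudyManifest, run_id: str,
) -> dict[str, list[float | None]]:
    """Per-metabolite, per-segment responses for one study run.

    Segments 1-6 carry the run's study samples (``None`` where the run is
    padded with blanks); segment 7 carries that run's QC draw.  Redundant
    satellite specs mirror their parent's responses (scaled at synthesis).
    """
    segs = design.segments(run_id)
    pivot = truth.response_pivot()
    qc = truth.qc_responses.set_index(["run_id", "metabolite"])["response"]
    out: dict[str, list[float | None]] = {}
    for spec in truth.specs:
        source = spec.is_redundant_of or spec.name
        responses: list[float | None] = []
        for s in segs:
            if s.is_qc:
                responses.append(float(qc.loc[(run_id, source)]))
            elif s.is_blank:
                responses.append(None)
            else:
                responses.append(float(pivot.loc[
                    (s.subject_id, s.timepoint, s.training_state), source]))
        out[spec.name] = responses
    return out


def truth_feature_matrix(truth: CohortTruth):
    """Ground-truth responses as a FeatureMatrix (metabolite-name keys).

    Bypasses the raw-signal round trip; useful for exercising the
    statistics and prognostic stages against the generative model directly.
    """
    from .feature_qc import FeatureMatrix  # local import avoids a cycle

    pivot = truth.response_pivot().reset_index()
    meta = pivot[["subject", "timepoint", "state"]].copy()
    meta["is_qc"] = False
    meta["run_id"] = ""
    values = pivot.drop(columns=["subject", "timepoint", "state"])
    values.columns.name = None
    return FeatureMatrix(meta, values)


DILUTION_LEVELS = (1.0, 0.5, 0.25, 0.125, 0.0625, 0.03125, 0.0)


def dilution_segment_responses(
    specs: Sequence[MetaboliteSpec],
    levels: Sequence[float] = DILUTION_LEVELS,
) -> dict[str, list[float | None]]:
    """Responses for one dilution-trend-filter run (pooled QC, serial
    2-fold dilutions ending in a blank).

    Behavior depends on each spec's ``dilution_behavior``: authentic
    features scale with the level and vanish in the blank; blank
    contaminants are level-independent and present in the blank; nonlinear
    junk is level-independent but blank-silent.
    """
    by_name = {s.name: s for s in specs}
    out: dict[str, list[float | None]] = {}
    for spec in specs:
        # satellites track their parent's behavior (area scaling happens
        # at synthesis time)
        src = by_name.get(spec.is_redundant_of or "", spec)
        responses: list[float | None] = []
        for lv in levels:
            if src.dilution_behavior == "blank_contaminant":
                responses.append(src.base_conc)
            elif src.dilution_behavior == "nonlinear":
                responses.append(src.base_conc if lv > 0 else None)
            else:
                responses.append(src.base_conc * lv if lv > 0 else None)
        out[spec.name] = responses
    return out
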