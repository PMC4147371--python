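"""Pipeline configuration: every tunable threshold in one validated place.

Defaults are the workflow's operating values: the 7-segment injection
format, 300-count peak floor, S/N >= 3 in the 8-30 min window, dilution
filter CV < 40% / R^2 > 0.90 / >= 3 levels with a silent blank, study
filter 75% detection / QC CV < 40%, volcano FC > 1.5 at p < 0.05,
Bonferroni at alpha 0.05, +-0.5 mM responder thresholds and an 8-variable
cap for stepwise regression.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    # design
    n_subjects: int = 11
    timepoints: list[int] = field(
        default_factory=lambda: [0, 20, 30, 60, 90, 120])
    states: list[str] = field(default_factory=lambda: ["naive", "trained"])
    # synthesis
    n_features: int = 55
    with_feature_universe: bool = True
    cv_analytical: float = 0.14
    cv_biological: float = 0.20
    baseline_sd: float = 100.0
    dilution_replicates: int = 3
    # peak picking
    min_height: float = 300.0
    snr_min: float = 3.0
    window_s: list[float] = field(default_factory=lambda: [480.0, 1800.0])
    spacing_tol: float = 0.3
    # feature curation
    cv_max: float = 0.40
    r2_min: float = 0.90
    min_levels: int = 3
    min_detect_frac: float = 0.75
    qc_cv_max: float = 0.40
    # statistics
    fc_thresh: float = 1.5
    p_thresh: float = 0.05
    alpha: float = 0.05
    n_components: int = 2
    bonferroni_family: int | None = None  # default: number of features tested
    # responder taxonomy / prognosis
    responder_thresh: float = 0.5
    max_vars: int = 8
    n_candidates: int = 6

    def __post_init__(self) -> None:
        checks = [
            ("n_subjects", self.n_subjects >= 1),
            ("timepoints", len(self.timepoints) >= 1),
            ("states", len(self.states) >= 1),
            ("cv_analytical", self.cv_analytical > 0),
            ("cv_biological", self.cv_biological > 0),
            ("baseline_sd", self.baseline_sd >= 0),
            ("min_height", self.min_height > 0),
            ("snr_min", self.snr_min >= 0),
            ("window_s", len(self.window_s) == 2
             and self.window_s[0] < self.window_s[1]),
            ("cv_max", 0 < self.cv_max <= 1),
            ("r2_min", 0 <= self.r2_min <= 1),
            ("min_levels", self.min_levels >= 1),
            ("min_detect_frac", 0 < self.min_detect_frac <= 1),
            ("qc_cv_max", 0 < self.qc_cv_max <= 1),
            ("fc_thresh", self.fc_thresh > 1),
            ("p_thresh", 0 < self.p_thresh < 1),
            ("alpha", 0 < self.alpha < 1),
            ("n_components", self.n_components >= 1),
            ("responder_thresh", self.responder_thresh > 0),
            ("max_vars", self.max_vars >= 1),
            ("dilution_replicates", self.dilution_replicates >= 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ConfigError(f"invalid config values for: {bad}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text))
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path.name}: expected a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)
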