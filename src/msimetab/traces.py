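"""In-memory containers for raw multiplexed electropherogram data.

A :class:`RawTrace` is one CE-MS run: a shared time axis plus one
:class:`IonChannel` (extracted-ion electropherogram) per m/z.  In
multi-segment injection CE-MS a single channel carries up to seven
time-ordered peaks, one per injected sample plug.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class IonChannel:
    """Per-m/z time-intensity series (an extracted ion electropherogram)."""

    mz: float
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class RawTrace:
    """One multiplexed run: channels keyed by m/z on a shared time grid."""

    run_id: str
    times: np.ndarray
    channels: dict[float, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def channel(self, mz: float) -> IonChannel:
        return IonChannel(mz, self.times, self.channels[mz])

    @property
    def mz_values(self) -> list[float]:
        return sorted(self.channels)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table ``run_id,mz,time_s,intensity``."""
        frames = [
            pd.DataFrame({
                "run_id": self.run_id,
                "mz": mz,
                "time_s": self.times,
                "intensity": inten,
            })
            for mz, inten in sorted(self.channels.items())
        ]
        return pd.concat(frames, ignore_index=True)

    def save(self, directory: str | Path) -> Path:
        """Write ``<run_id>.csv`` plus a JSON sidecar of channel metadata."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{self.run_id}.csv"
        self.to_frame().to_csv(csv_path, index=False, float_format="%.6g")
        sidecar = {
            "run_id": self.run_id,
            "n_points": int(self.times.size),
            "mz_values": [float(m) for m in self.mz_values],
            "meta": self.meta,
        }
        (directory / f"{self.run_id}.json").write_text(
            json.dumps(sidecar, indent=1))
        return csv_path

    @classmethod
    def load(cls, csv_path: str | Path) -> "RawTrace":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        required = {"run_id", "mz", "time_s", "intensity"}
        if not required.issubset(df.columns):
            raise ValueError(
                f"{csv_path.name}: expected columns {sorted(required)}")
        run_id = str(df["run_id"].iloc[0])
        channels: dict[float, np.ndarray] = {}
        times: np.ndarray | None = None
        for mz, grp in df.groupby("mz"):
            t = grp["time_s"].to_numpy()
            if times is None:
                times = t
            channels[float(mz)] = grp["intensity"].to_numpy()
        meta = {}
        sidecar = csv_path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text()).get("meta", {})
        return cls(run_id=run_id, times=times, channels=channels, meta=meta)
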