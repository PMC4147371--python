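"""Signal processing for multiplexed serial-injection electropherograms.

Inverts the raw-signal model: extract ion traces, detect peaks, assign each
peak to the injected sample plug it came from, and normalize against the
per-segment internal standard to get relative migration times (RMT) and
relative peak areas (RPA).  Co-migrating redundant ions (isotopes, adducts,
in-source losses) are rejected so each metabolite is counted once.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .study_design import SampleMeta
from .synthetic import (IS_MZ, REDUNDANCY_OFFSETS, InjectionProgram,
                        default_injection_program)
from .traces import IonChannel, RawTrace

DEFAULT_MIN_HEIGHT = 300.0       # counts
DEFAULT_SNR_MIN = 3.0
DEFAULT_WINDOW = (480.0, 1800.0)  # s; excludes salt front and EOF regions


class AmbiguousAssignmentError(ValueError):
    """More peaks in a channel window than injected sample plugs."""


class NormalizationError(ValueError):
    """Internal standard missing in a segment that has analyte signal."""


@dataclass(frozen=True)
class Peak:
    mz: float
    apex_time: float
    area: float
    height: float
    snr: float
    segment_index: int | None = None  # 1-based; None = unassigned

    def __post_init__(self) -> None:
        if self.height <= 0 or self.area <= 0:
            raise ValueError("peak height and area must be positive")
        if self.snr < 0:
            raise ValueError("snr must be >= 0")


@dataclass(frozen=True)
class NormalizedResponse:
    """One segment-level measurement keyed by m/z:RMT."""

    mz: float
    segment_index: int
    rmt: float   # analyte apex / IS apex, same segment
    rpa: float   # analyte area / IS area, same segment
    sample: SampleMeta | None = None

    @property
    def metabolite_key(self) -> str:
        return f"{self.mz:.3f}:{self.rmt:.3f}"


def extract_eic(raw: RawTrace, mz: float, tol_ppm: float = 10.0) -> IonChannel:
    """Extracted-ion electropherogram: sum of channels within +-tol_ppm.

    Returns an all-zero trace on the run's time grid when no channel
    matches.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    tol = mz * tol_ppm * 1e-6
    total = np.zeros_like(raw.times)
    for cmz, intens in raw.channels.items():
        if abs(cmz - mz) <= tol:
            total = total + intens
    return IonChannel(mz=mz, times=raw.times, intensities=total)


def _baseline_sd(intensities: np.ndarray) -> float:
    # noise estimated from the quiet part of the trace: points below the
    # 20th intensity percentile
    q20 = np.percentile(intensities, 20)
    quiet = intensities[intensities <= q20]
    return float(quiet.std()) if quiet.size > 1 else 0.0


def detect_peaks(
    channel: IonChannel,
    min_height: float = DEFAULT_MIN_HEIGHT,
    snr_min: float = DEFAULT_SNR_MIN,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> list[Peak]:
    """Local maxima above the height and S/N floors inside the time window.

    Peak area is trapezoidal between the flanking local minima; S/N is
    height over the baseline SD estimated from signal-free regions.
    """
    t, y = channel.times, channel.intensities
    if t.size < 3:
        return []
    noise_sd = _baseline_sd(y)
    idx, _ = find_peaks(y, height=min_height)
    lo, hi = window
    idx = idx[(t[idx] >= lo) & (t[idx] <= hi)]
    if idx.size == 0:
        return []

    # integration bounds: flanking local minima, additionally capped at
    # +-4 sigma (sigma from the half-height width) so the tail of a
    # neighbouring train's peak is not swept into the area
    bounds = np.concatenate(([0], idx, [t.size - 1]))
    step = float(np.median(np.diff(t)))
    peaks = []
    for j, i in enumerate(idx):
        left_lim = bounds[j]
        right_lim = bounds[j + 2]
        left = left_lim + int(np.argmin(y[left_lim:i + 1]))
        right = i + int(np.argmin(y[i:right_lim + 1]))
        if right <= left:
            continue
        half = y[i] / 2.0
        li = i
        while li > left and y[li] > half:
            li -= 1
        ri = i
        while ri < right and y[ri] > half:
            ri += 1
        sigma_est = max((t[ri] - t[li]) / 2.3548, step)
        cap = int(round(4.0 * sigma_est / step))
        left = max(left, i - cap)
        right = min(right, i + cap)
        area = float(np.trapezoid(y[left:right + 1], t[left:right + 1]))
        height = float(y[i])
        snr = height / noise_sd if noise_sd > 0 else float("inf")
        if snr < snr_min or area <= 0:
            continue
        peaks.append(Peak(mz=channel.mz, apex_time=float(t[i]),
                          area=area, height=height, snr=snr))
    return peaks


def assign_segments(
    peaks: Sequence[Peak],
    program: InjectionProgram | None = None,
    expected_spacing: float = 25.0,
    spacing_tol: float = 0.3,
) -> list[Peak]:
    """Label one metabolite's peaks with their injection segment (1..7).

    Peaks are ordered by apex time; the earliest is anchored at segment 1
    and gaps wider than ``(1 + spacing_tol) x expected_spacing`` advance the
    segment counter by the number of missed plugs.  Peaks that fall past the
    last segment are flagged unassigned (``segment_index None``).
    """
    program = program or default_injection_program()
    n_slots = program.n_samples
    ordered = sorted(peaks, key=lambda p: p.apex_time)
    if len(ordered) > n_slots:
        apexes = [round(p.apex_time, 1) for p in ordered]
        raise AmbiguousAssignmentError(
            f"{len(ordered)} peaks for {n_slots} segments: apexes {apexes}")
    assigned: list[Peak] = []
    seg = 1
    prev_apex: float | None = None
    for p in ordered:
        if prev_apex is not None:
            gap = p.apex_time - prev_apex
            if gap <= (1 + spacing_tol) * expected_spacing:
                seg += 1
            else:
                seg += max(2, round(gap / expected_spacing))
        assigned.append(replace(
            p, segment_index=seg if seg <= n_slots else None))
        prev_apex = p.apex_time
    return assigned


def normalize(
    peaks: Iterable[Peak],
    is_peaks: Iterable[Peak],
    samples: dict[int, SampleMeta] | None = None,
) -> list[NormalizedResponse]:
    """Per-segment RMT and RPA against the same segment's internal standard.

    The internal standard travels in every plug, so normalizing apex time
    and area segment-by-segment cancels migration drift and injection-volume
    variation.
    """
    is_by_seg = {p.segment_index: p for p in is_peaks
                 if p.segment_index is not None}
    out = []
    for p in peaks:
        if p.segment_index is None:
            continue
        ref = is_by_seg.get(p.segment_index)
        if ref is None:
            raise NormalizationError(
                f"no internal standard in segment {p.segment_index} "
                f"(analyte m/z {p.mz:.4f})")
        out.append(NormalizedResponse(
            mz=p.mz, segment_index=p.segment_index,
            rmt=p.apex_time / ref.apex_time,
            rpa=p.area / ref.area,
            sample=None if samples is None else samples.get(p.segment_index)))
    return out


def reject_redundant(
    features: Sequence[tuple[float, float, float]],
    rmt_tol: float = 0.01,
    mass_tol_ppm: float = 10.0,
) -> tuple[list[tuple[float, float, float]], list[tuple[float, float, float]]]:
    """Partition (mz, rmt, response) features into (kept, redundant).

    Two features are linked when they co-migrate (|delta RMT| <= rmt_tol)
    and their m/z difference matches a known satellite offset (13C isotope,
    sodium adduct, ammonia or water loss) within ``mass_tol_ppm``.  In each
    linked group only the highest-response member is kept.  A feature with
    no co-migrating partner is never removed.
    """
    n = len(features)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        parent[find(i)] = find(j)

    offsets = list(REDUNDANCY_OFFSETS.values())
    for i in range(n):
        mz_i, rmt_i, _ = features[i]
        for j in range(i + 1, n):
            mz_j, rmt_j, _ = features[j]
            if abs(rmt_i - rmt_j) > rmt_tol:
                continue
            diff = abs(mz_j - mz_i)
            tol = max(mz_i, mz_j) * mass_tol_ppm * 1e-6
            if any(abs(diff - abs(off)) <= tol for off in offsets):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    kept, redundant = [], []
    for members in groups.values():
        best = max(members, key=lambda i: features[i][2])
        for i in members:
            (kept if i == best else redundant).append(features[i])
    kept.sort(key=lambda f: (f[0], f[1]))
    redundant.sort(key=lambda f: (f[0], f[1]))
    return kept, redundant


def split_trains(
    peaks: Sequence[Peak],
    t_is: float,
    spacing: float,
    n_slots: int = 7,
    match_frac: float = 0.2,
) -> list[list[Peak]]:
    """Separate a channel's peaks into per-metabolite injection trains.

    Isobaric metabolites (e.g. Leu and Ile) share a channel, each
    contributing its own train of up to ``n_slots`` peaks.  The earliest
    unclaimed peak anchors a new train; its apparent RMT predicts the
    train's remaining plug positions (``rmt x (t_is + k x spacing)``) and
    unclaimed peaks within ``match_frac`` of the plug spacing of a
    prediction join the train.
    """
    remaining = sorted(peaks, key=lambda p: p.apex_time)
    trains: list[list[Peak]] = []
    while remaining:
        anchor = remaining.pop(0)
        rmt0 = anchor.apex_time / t_is
        tol = match_frac * spacing * rmt0
        train = [anchor]
        for k in range(1, n_slots):
            target = rmt0 * (t_is + k * spacing)
            best = None
            for p in remaining:
                if abs(p.apex_time - target) <= tol and (
                        best is None or abs(p.apex_time - target)
                        < abs(best.apex_time - target)):
                    best = p
            if best is not None:
                train.append(best)
                remaining.remove(best)
        trains.append(train)
    return trains


def assign_feature_keys(
    table: pd.DataFrame,
    mz_decimals: int = 4,
    rmt_gap: float = 0.004,
) -> pd.DataFrame:
    """Attach m/z:RMT feature keys to an assigned-peak table.

    Rows are grouped by rounded m/z, then split into RMT clusters wherever
    consecutive sorted RMT values jump by more than ``rmt_gap`` (isobaric
    metabolites are distinct features).  The key is
    ``"{mz:.3f}:{median rmt:.3f}"``.
    """
    table = table.copy()
    table["mz_group"] = table["mz"].round(mz_decimals)
    keys = pd.Series(index=table.index, dtype=object)
    for g, grp in table.groupby("mz_group"):
        order = grp["rmt"].sort_values()
        breaks = order.diff() > rmt_gap
        cluster_ids = breaks.cumsum()
        for cid in cluster_ids.unique():
            members = order.index[cluster_ids == cid]
            med = float(order.loc[members].median())
            keys.loc[members] = f"{g:.3f}:{med:.3f}"
    table["key"] = keys
    return table.drop(columns=["mz_group"])


def process_run(
    raw: RawTrace,
    program: InjectionProgram | None = None,
    min_height: float = DEFAULT_MIN_HEIGHT,
    snr_min: float = DEFAULT_SNR_MIN,
    window: tuple[float, float] = DEFAULT_WINDOW,
    spacing_tol: float = 0.3,
) -> pd.DataFrame:
    """One run end to end: detect, split trains, assign and normalize.

    Returns the assigned-peak table with columns
    ``run_id, mz, rmt, segment, area, height, snr, rpa``.  The internal
    standard's observed apex and plug spacing calibrate the expected
    positions for every analyte train, scaled by each train's apparent
    RMT (a slower analyte's plugs arrive proportionally further apart).
    """
    program = program or default_injection_program()
    base_spacing = float(raw.meta.get("migration_offset_s", 25.0))

    is_channel = extract_eic(raw, IS_MZ)
    is_detected = detect_peaks(is_channel, min_height, snr_min, window)
    is_assigned = assign_segments(is_detected, program, base_spacing,
                                  spacing_tol)
    if not is_assigned:
        raise NormalizationError(f"{raw.run_id}: no internal standard found")
    t_is_obs = min(p.apex_time for p in is_assigned)
    is_apexes = sorted(p.apex_time for p in is_assigned)
    if len(is_apexes) > 1:
        base_spacing = (is_apexes[-1] - is_apexes[0]) / (len(is_apexes) - 1)

    rows = []
    for mz in raw.mz_values:
        if abs(mz - IS_MZ) <= IS_MZ * 10e-6:
            continue
        channel = raw.channel(mz)
        detected = detect_peaks(channel, min_height, snr_min, window)
        if not detected:
            continue
        for train in split_trains(detected, t_is_obs, base_spacing,
                                  program.n_samples):
            rmt0 = train[0].apex_time / t_is_obs
            assigned = assign_segments(train, program,
                                       base_spacing * rmt0, spacing_tol)
            by_seg = {p.segment_index: p for p in assigned
                      if p.segment_index is not None}
            for resp in normalize(assigned, is_assigned):
                peak = by_seg[resp.segment_index]
                rows.append({"run_id": raw.run_id, "mz": mz,
                             "rmt": resp.rmt, "segment": resp.segment_index,
                             "area": peak.area, "height": peak.height,
                             "snr": peak.snr, "rpa": resp.rpa})
    return pd.DataFrame(rows, columns=["run_id", "mz", "rmt", "segment",
                                       "area", "height", "snr", "rpa"])
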