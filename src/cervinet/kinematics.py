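"""Per-movement kinematic summaries from raw neck-angle traces.

A recording is a 45-s self-paced oscillation between the ROM limits of a
movement.  The trace is segmented into repetitions (one per prominent
peak), and each movement is summarized by the mean per-repetition ROM, the
coefficient of variation (CV) of those ROMs, the mean speed to peak, and
the ROM normalized by an age-specific normative value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .nfhas import MOVEMENTS

__all__ = [
    "AngleTrace",
    "RepetitionMetrics",
    "MovementSummary",
    "segment_repetitions",
    "summarize_movement",
    "angular_velocity",
    "normative_rom",
    "read_trace_csv",
    "write_trace_csv",
    "read_normative_table",
    "DEFAULT_NORMATIVE_ROM",
]


class InsufficientDataError(ValueError):
    """Not enough repetitions (or samples) to summarize an assessment."""


@dataclass(frozen=True)
class AngleTrace:
    """One movement recording: head-to-thorax angle sampled over time.

    ``time`` is in seconds and strictly increasing; ``angle`` in degrees
    with magnitude at most 180.
    """

    movement: str
    time: np.ndarray
    angle: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.angle, dtype=float)
        if self.movement not in MOVEMENTS:
            raise ValueError(f"unknown movement id {self.movement!r}")
        if t.ndim != 1 or a.shape != t.shape or t.size < 2:
            raise ValueError("trace needs >= 2 aligned (time, angle) samples")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.max(np.abs(a)) > 180.0:
            raise ValueError("angles must lie within [-180, 180] degrees")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "angle", a)


@dataclass(frozen=True)
class RepetitionMetrics:
    rom: float  # degrees
    peak_speed: float  # deg/s, on the excursion toward the peak
    duration: float  # s

    def __post_init__(self) -> None:
        if self.rom < 0 or self.peak_speed < 0:
            raise ValueError("rom and peak_speed must be non-negative")


@dataclass(frozen=True)
class MovementSummary:
    movement: str
    mean_rom: float  # degrees
    rom_normalized: float  # percent of normative
    cv: float  # percent
    speed_to_peak: float  # deg/s
    n_repetitions: int

    def __post_init__(self) -> None:
        if self.cv < 0 or self.rom_normalized < 0 or self.n_repetitions < 1:
            raise ValueError("invalid movement summary")


def angular_velocity(trace: AngleTrace) -> np.ndarray:
    """Finite-difference angular velocity, deg/s (central; one-sided ends)."""
    return np.gradient(trace.angle, trace.time)


def segment_repetitions(
    trace: AngleTrace,
    prominence: float = 5.0,
    min_half_period: float = 0.3,
) -> list[RepetitionMetrics]:
    """Split a trace into repetitions, one per prominent peak.

    A repetition window runs from the preceding trough (or the trace start)
    to the following trough (or the trace end).  Within the window, ROM is
    the max-min angle excursion, and peak speed is the largest absolute
    finite-difference velocity between the window start and the peak.

    Returns an empty list when no full oscillation is present; the caller
    decides whether to reject the assessment.
    """
    if prominence <= 0 or min_half_period <= 0:
        raise ValueError("prominence and min_half_period must be positive")
    angle = trace.angle
    t = trace.time
    dt = np.median(np.diff(t))
    distance = max(1, int(round(min_half_period / dt)))
    peaks, _ = find_peaks(angle, prominence=prominence, distance=distance)
    troughs, _ = find_peaks(-angle, prominence=prominence, distance=distance)
    if peaks.size == 0:
        return []
    velocity = angular_velocity(trace)
    reps: list[RepetitionMetrics] = []
    for p in peaks:
        before = troughs[troughs < p]
        after = troughs[troughs > p]
        lo = int(before[-1]) if before.size else 0
        hi = int(after[0]) if after.size else angle.size - 1
        window = angle[lo : hi + 1]
        rom = float(window.max() - window.min())
        peak_speed = float(np.max(np.abs(velocity[lo : p + 1])))
        reps.append(
            RepetitionMetrics(rom=rom, peak_speed=peak_speed, duration=float(t[hi] - t[lo]))
        )
    return reps


def summarize_movement(
    reps: Sequence[RepetitionMetrics],
    movement: str,
    normative_rom_deg: float,
) -> MovementSummary:
    """Aggregate repetitions into one movement summary.

    CV is the sample standard deviation of per-repetition ROMs over their
    mean, in percent; a single repetition yields CV = 0 by convention so
    downstream z-scoring never sees missing values.
    """
    if len(reps) == 0:
        raise InsufficientDataError(f"no repetitions for movement {movement}")
    if normative_rom_deg <= 0:
        raise ValueError("normative ROM must be positive")
    roms = np.array([r.rom for r in reps], dtype=float)
    speeds = np.array([r.peak_speed for r in reps], dtype=float)
    mean_rom = float(roms.mean())
    if roms.size > 1 and mean_rom > 0:
        cv = 100.0 * float(roms.std(ddof=1)) / mean_rom
    else:
        cv = 0.0
    return MovementSummary(
        movement=movement,
        mean_rom=mean_rom,
        rom_normalized=100.0 * mean_rom / normative_rom_deg,
        cv=cv,
        speed_to_peak=float(speeds.mean()),
        n_repetitions=len(reps),
    )


# Normative active cervical ROM (degrees) by age band.  The normative table
# is configuration: this default, in the range clinical goniometry studies
# report for healthy adults, ships for the synthetic pipeline and can be
# replaced by a user CSV (columns age_band, movement, normative_deg with
# age bands written "lo-hi").
DEFAULT_NORMATIVE_ROM: dict[str, dict[str, float]] = {
    "18-34": {"F": 60.0, "E": 70.0, "Llb": 45.0, "Rlb": 45.0, "Lrt": 75.0, "Rrt": 75.0},
    "35-49": {"F": 55.0, "E": 65.0, "Llb": 41.0, "Rlb": 41.0, "Lrt": 70.0, "Rrt": 70.0},
    "50-64": {"F": 50.0, "E": 58.0, "Llb": 36.0, "Rlb": 36.0, "Lrt": 65.0, "Rrt": 65.0},
    "65-120": {"F": 45.0, "E": 52.0, "Llb": 31.0, "Rlb": 31.0, "Lrt": 60.0, "Rrt": 60.0},
}


def _band_bounds(band: str) -> tuple[float, float]:
    lo, hi = band.split("-")
    return float(lo), float(hi)


def normative_rom(
    movement: str,
    age: float,
    table: dict[str, dict[str, float]] | None = None,
) -> float:
    """Normative ROM in degrees for a movement at a given age."""
    table = DEFAULT_NORMATIVE_ROM if table is None else table
    for band, values in table.items():
        lo, hi = _band_bounds(band)
        if lo <= age <= hi:
            return values[movement]
    # outside every band: clamp to the nearest one
    bands = sorted(table, key=lambda b: _band_bounds(b)[0])
    band = bands[0] if age < _band_bounds(bands[0])[0] else bands[-1]
    return table[band][movement]


def read_normative_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a normative-ROM CSV (age_band, movement, normative_deg)."""
    df = pd.read_csv(path)
    table: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        table.setdefault(str(row["age_band"]), {})[str(row["movement"])] = float(
            row["normative_deg"]
        )
    return table


def read_trace_csv(path: str | Path, movement: str) -> AngleTrace:
    df = pd.read_csv(path)
    return AngleTrace(
        movement=movement,
        time=df["time_s"].to_numpy(float),
        angle=df["angle_deg"].to_numpy(float),
    )


def write_trace_csv(trace: AngleTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time, "angle_deg": trace.angle}).to_csv(
        path, index=False
    )
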