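"""Domain types and file I/O for raw respirometry traces and metadata.

A :class:`RespirometryTrace` is a synchronized multi-channel time series
recorded from a multiplexed push-mode respirometry system: O2 and CO2
concentrations (percent), water vapor pressure and barometric pressure
(kPa), flow rate (ml min^-1), and an integer marker saying which chamber
is routed to the analyzers at each sample.  Channel 0 is the empty
baseline (control) chamber.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from respicall.errors import ScheduleError, TraceFormatError, TraceValidationError

BASELINE_CHANNEL = 0
MAX_REPETITIONS = 3

#: Column order of the native long-form trace CSV.
TRACE_COLUMNS = (
    "time_s",
    "o2_pct",
    "co2_pct",
    "wvp_kpa",
    "bp_kpa",
    "fr_ml_min",
    "channel",
)

#: Column order of the native metadata CSV.
METADATA_COLUMNS = ("individual_id", "mass_g", "date", "year", "temp_c", "pond")


@dataclass
class TraceDialect:
    """Mapping from native column names to the names used in a CSV export.

    The default dialect is the identity mapping onto :data:`TRACE_COLUMNS`.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in TRACE_COLUMNS}
    )

    def rename_map(self) -> dict[str, str]:
        """File column name -> native column name."""
        return {v: k for k, v in self.columns.items()}


@dataclass
class RespirometryTrace:
    """Uniformly sampled multi-channel respirometry recording.

    Parameters
    ----------
    time_s : array of float
        Seconds from recording start; strictly increasing, constant step.
    o2_pct, co2_pct : array of float
        Gas concentrations in percent.
    wvp_kpa, bp_kpa : array of float
        Water vapor pressure and barometric pressure in kPa.
    fr_ml_min : array of float
        Measured (uncorrected) flow rate in ml min^-1.
    channel : array of int
        Active chamber id per sample; 0 is the baseline chamber.
    """

    time_s: np.ndarray
    o2_pct: np.ndarray
    co2_pct: np.ndarray
    wvp_kpa: np.ndarray
    bp_kpa: np.ndarray
    fr_ml_min: np.ndarray
    channel: np.ndarray

    def __post_init__(self) -> None:
        for name in TRACE_COLUMNS:
            arr = np.asarray(getattr(self, name))
            if name == "channel":
                arr = arr.astype(np.int64)
            else:
                arr = arr.astype(np.float64)
            setattr(self, name, arr)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.time_s)
        for name in TRACE_COLUMNS:
            if len(getattr(self, name)) != n:
                raise TraceValidationError(
                    f"channel '{name}' has length {len(getattr(self, name))}, "
                    f"expected {n}"
                )
        if n < 2:
            raise TraceValidationError("trace needs at least 2 samples")
        steps = np.diff(self.time_s)
        if np.any(steps <= 0):
            raise TraceValidationError("time must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise TraceValidationError("time step must be constant")
        if np.any(self.fr_ml_min <= 0):
            raise TraceValidationError("flow rate must be positive")
        if np.any(self.wvp_kpa < 0) or np.any(self.wvp_kpa >= self.bp_kpa):
            raise TraceValidationError("require 0 <= WVP < BP")
        if np.any(self.o2_pct <= 0) or np.any(self.o2_pct >= 100):
            raise TraceValidationError("O2 percent must lie in (0, 100)")

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return float(self.time_s[1] - self.time_s[0])

    @property
    def n_samples(self) -> int:
        return len(self.time_s)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + self.dt

    def copy(self) -> "RespirometryTrace":
        return replace(
            self, **{c: getattr(self, c).copy() for c in TRACE_COLUMNS}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRACE_COLUMNS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RespirometryTrace":
        return cls(**{c: df[c].to_numpy() for c in TRACE_COLUMNS})


@dataclass(frozen=True)
class ScheduleSegment:
    """One contiguous dwell of the multiplexer on a single channel."""

    channel: int
    start_s: float
    end_s: float
    repetition: int
    short: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_baseline(self) -> bool:
        return self.channel == BASELINE_CHANNEL


@dataclass
class ChannelSchedule:
    """Ordered, contiguous, non-overlapping channel dwell segments."""

    segments: list[ScheduleSegment]

    def __post_init__(self) -> None:
        for a, b in zip(self.segments, self.segments[1:]):
            if b.start_s != a.end_s:
                raise ScheduleError(
                    f"segments not contiguous at t={a.end_s} -> {b.start_s}"
                )

    def animal_segments(self, include_short: bool = False) -> list[ScheduleSegment]:
        return [
            s
            for s in self.segments
            if not s.is_baseline and (include_short or not s.short)
        ]

    def baseline_segments(self, include_short: bool = False) -> list[ScheduleSegment]:
        return [
            s
            for s in self.segments
            if s.is_baseline and (include_short or not s.short)
        ]

    def channels(self) -> list[int]:
        return sorted({s.channel for s in self.segments if not s.is_baseline})

    @property
    def starts_with_baseline(self) -> bool:
        return bool(self.segments) and self.segments[0].is_baseline

    @property
    def ends_with_baseline(self) -> bool:
        return bool(self.segments) and self.segments[-1].is_baseline


@dataclass
class IndividualRecord:
    """One individual's metadata at a capture/measurement event."""

    individual_id: str
    mass_g: float
    date: pd.Timestamp
    year: int
    temp_c: float
    pond: str = ""

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date)
        if self.mass_g <= 0:
            raise TraceValidationError("mass_g must be positive")
        if not 10.0 <= self.temp_c <= 35.0:
            raise TraceValidationError(
                f"temperature {self.temp_c} outside plausible range [10, 35] C"
            )

    @property
    def calendar_day(self) -> int:
        """ISO day-of-year of the capture/recording night."""
        return int(self.date.dayofyear)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace(path, dialect: TraceDialect | None = None) -> RespirometryTrace:
    """Read a trace CSV.

    Raises :class:`TraceFormatError` when required columns are missing and
    :class:`TraceValidationError` when the content violates invariants.
    """
    dialect = dialect or TraceDialect()
    df = pd.read_csv(path, float_precision="round_trip")
    rename = dialect.rename_map()
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    df = df.rename(columns=rename)
    return RespirometryTrace.from_frame(df)


def write_trace(trace: RespirometryTrace, path) -> None:
    """Write a trace in the native CSV dialect (lossless round-trip)."""
    # %.17g guarantees float64 round-trips bit-exactly through text
    trace.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_metadata(path) -> pd.DataFrame:
    """Read the individual-metadata CSV; adds a derived ``calendar_day``."""
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    df = df.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["calendar_day"] = df["date"].dt.dayofyear
    if (df["mass_g"] <= 0).any():
        raise TraceValidationError("mass_g must be positive")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


# ---------------------------------------------------------------------------
# Schedule inference
# ---------------------------------------------------------------------------

def infer_schedule(
    trace: RespirometryTrace, min_dwell_s: float = 120.0
) -> ChannelSchedule:
    """Run-length encode the channel marker into a :class:`ChannelSchedule`.

    Repetition indices are assigned 1..3 per channel in temporal order
    (baseline occurrences are numbered too but unbounded).  Segments
    shorter than ``min_dwell_s`` are flagged ``short``; an animal channel
    appearing more than three times raises :class:`ScheduleError`.
    """
    ch = trace.channel
    dt = trace.dt
    boundaries = np.flatnonzero(np.diff(ch)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [len(ch)]))

    counts: dict[int, int] = {}
    segments: list[ScheduleSegment] = []
    for i0, i1 in zip(starts, ends):
        c = int(ch[i0])
        counts[c] = counts.get(c, 0) + 1
        if c != BASELINE_CHANNEL and counts[c] > MAX_REPETITIONS:
            raise ScheduleError(
                f"channel {c} appears more than {MAX_REPETITIONS} times"
            )
        start_s = float(trace.time_s[i0])
        end_s = float(trace.time_s[i1 - 1]) + dt
        segments.append(
            ScheduleSegment(
                channel=c,
                start_s=start_s,
                end_s=end_s,
                repetition=counts[c],
                short=(i1 - i0) * dt < min_dwell_s,
            )
        )
    return ChannelSchedule(segments=segments)


def segment_slice(trace: RespirometryTrace, seg: ScheduleSegment) -> slice:
    """Index slice of ``trace`` covered by schedule segment ``seg``."""
    i0 = int(np.searchsorted(trace.time_s, seg.start_s, side="left"))
    i1 = int(np.searchsorted(trace.time_s, seg.end_s - 0.5 * trace.dt, side="right"))
    return slice(i0, i1)
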