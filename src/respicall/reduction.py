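"""Reduce a raw multiplexed trace to per-repetition oxygen-consumption series.

Stages, in order: integer-sample lag alignment of the gas channels against
the water-vapor channel, drift (baseline) correction through the empty
control chamber, sign-flip/proportional conversion, water-vapor flow
correction, and the oxygen-consumption computation

    FRd  = FR * (BP - WVP) / BP
    VO2  = 60 * FRd * dO2 / (1 - FeO2),   FeO2 = FiO2_ref - dO2

with VO2 in ml h^-1 for flow in ml min^-1 and fractional concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from respicall.errors import ReductionDomainError, TraceValidationError
from respicall.model import (
    ChannelSchedule,
    RespirometryTrace,
    ScheduleSegment,
    infer_schedule,
    segment_slice,
)

FLAG_LAG_UNDETERMINED = "lag_undetermined"
FLAG_LAG_AT_BOUND = "lag_at_bound"
FLAG_EXTRAPOLATED_BASELINE = "extrapolated_baseline"
FLAG_SHORT_SEGMENT = "short_segment"


@dataclass
class ReductionParams:
    """Tunable constants of the reduction.

    ``fio2_ref`` is the incurrent fractional O2 concentration used in the
    excurrent-fraction denominator; after flat-baselining, referencing the
    deflection to the baseline or to ``fio2_ref`` is equivalent.
    ``washout_s`` samples are discarded after every channel switch to let
    the analyzer stream settle (0 keeps every sample).
    """

    fio2_ref: float = 0.2095
    lag_max_s: float = 30.0
    washout_s: float = 60.0
    baseline_mode: str = "linear"  # or "spline"
    lag_override: dict[str, int] | None = None  # {"o2": n, "co2": n} samples

    def __post_init__(self) -> None:
        if not 0.0 < self.fio2_ref < 1.0:
            raise ValueError("fio2_ref must lie in (0, 1)")
        if self.lag_max_s < 0:
            raise ValueError("lag_max_s must be >= 0")
        if self.washout_s < 0:
            raise ValueError("washout_s must be >= 0")
        if self.baseline_mode not in ("linear", "spline"):
            raise ValueError("baseline_mode must be 'linear' or 'spline'")


@dataclass
class LagReport:
    """Estimated integer-sample shifts applied to the gas channels."""

    shifts: dict[str, int] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)


@dataclass
class Vo2Series:
    """Baseline-corrected oxygen-consumption series for one repetition."""

    channel: int
    repetition: int
    time_s: np.ndarray
    vo2_ml_h: np.ndarray
    fr_d_ml_min: np.ndarray
    flags: list[str] = field(default_factory=list)
    sample_flagged: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.vo2_ml_h = np.asarray(self.vo2_ml_h, dtype=np.float64)
        self.fr_d_ml_min = np.asarray(self.fr_d_ml_min, dtype=np.float64)
        if len(self.time_s) == 0:
            raise TraceValidationError("empty Vo2Series")
        if not np.all(np.isfinite(self.vo2_ml_h)):
            raise TraceValidationError("vo2_ml_h must be finite")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if len(self.time_s) > 1 else 1.0

    def __len__(self) -> int:
        return len(self.time_s)


# ---------------------------------------------------------------------------
# Lag correction
# ---------------------------------------------------------------------------

def _estimate_lag(
    reference: np.ndarray, signal: np.ndarray, max_lag: int
) -> tuple[int, float]:
    """Integer lag of ``signal`` behind ``reference``.

    Maximizes the absolute Pearson correlation between the first
    differences of the two series over lags in [-max_lag, max_lag].
    Returns (lag, peak absolute correlation); correlation 0 when either
    difference series is flat.
    """
    dref = np.diff(reference)
    dsig = np.diff(signal)
    if np.allclose(dref, 0) or np.allclose(dsig, 0):
        return 0, 0.0
    dref = dref - dref.mean()
    dsig = dsig - dsig.mean()
    denom = np.sqrt((dref**2).sum() * (dsig**2).sum())
    if denom == 0:
        return 0, 0.0
    best_lag, best_r = 0, -1.0
    n = len(dref)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            a, b = dref[: n - lag], dsig[lag:]
        else:
            a, b = dref[-lag:], dsig[: n + lag]
        if len(a) < 2:
            continue
        r = abs(float(np.dot(a, b))) / denom
        if r > best_r:
            best_lag, best_r = lag, r
    return best_lag, best_r


def _shift_left(x: np.ndarray, k: int) -> np.ndarray:
    """Advance a delayed signal by k samples, padding the tail edge."""
    if k == 0:
        return x.copy()
    out = np.empty_like(x)
    if k > 0:
        out[:-k] = x[k:]
        out[-k:] = x[-1]
    else:
        out[-k:] = x[:k]
        out[:-k] = x[0]
    return out


def correct_lag(
    trace: RespirometryTrace, params: ReductionParams
) -> tuple[RespirometryTrace, LagReport]:
    """Align the O2 and CO2 channels to the water-vapor channel.

    The gas analyzers sit downstream of the water-vapor cell, so their
    step responses at channel switches trail the WVP channel by a few
    samples.  The lag is the integer shift maximizing the cross-correlation
    of first differences; channels with no usable transients are left
    unshifted with a warning flag, as are lags that hit the search bound.
    Manual per-channel overrides (samples) bypass estimation entirely.
    """
    max_lag = int(round(params.lag_max_s / trace.dt))
    report = LagReport()
    out = trace.copy()
    for name in ("o2", "co2"):
        arr = getattr(out, f"{name}_pct")
        if params.lag_override and name in params.lag_override:
            k = int(params.lag_override[name])
            report.shifts[name] = k
            setattr(out, f"{name}_pct", _shift_left(arr, k))
            continue
        lag, peak = _estimate_lag(trace.wvp_kpa, arr, max_lag)
        if peak < 0.05:
            report.shifts[name] = 0
            report.flags[name] = FLAG_LAG_UNDETERMINED
            continue
        if abs(lag) >= max_lag > 0:
            report.shifts[name] = 0
            report.flags[name] = FLAG_LAG_AT_BOUND
            continue
        report.shifts[name] = lag
        setattr(out, f"{name}_pct", _shift_left(arr, lag))
    return out, report


# ---------------------------------------------------------------------------
# Baseline / drift correction
# ---------------------------------------------------------------------------

def _washout_slice(trace: RespirometryTrace, seg: ScheduleSegment, washout_s: float) -> slice:
    sl = segment_slice(trace, seg)
    skip = int(round(washout_s / trace.dt))
    start = min(sl.start + skip, sl.stop)
    return slice(start, sl.stop)


def _drift_curve(
    t_anchor: np.ndarray, v_anchor: np.ndarray, t_eval: np.ndarray, mode: str
) -> np.ndarray:
    if len(t_anchor) == 1:
        return np.full_like(t_eval, v_anchor[0], dtype=float)
    if mode == "spline" and len(t_anchor) >= 4:
        from scipy.interpolate import CubicSpline

        return CubicSpline(t_anchor, v_anchor)(t_eval)
    out = np.interp(t_eval, t_anchor, v_anchor)
    # linear extrapolation beyond the outermost anchors (np.interp clamps,
    # which would leave a systematic residual inside the edge baselines)
    lo = t_eval < t_anchor[0]
    if np.any(lo):
        s = (v_anchor[1] - v_anchor[0]) / (t_anchor[1] - t_anchor[0])
        out[lo] = v_anchor[0] + s * (t_eval[lo] - t_anchor[0])
    hi = t_eval > t_anchor[-1]
    if np.any(hi):
        s = (v_anchor[-1] - v_anchor[-2]) / (t_anchor[-1] - t_anchor[-2])
        out[hi] = v_anchor[-1] + s * (t_eval[hi] - t_anchor[-1])
    return out


def baseline_correct(
    trace: RespirometryTrace,
    schedule: ChannelSchedule,
    params: ReductionParams,
) -> tuple[np.ndarray, np.ndarray, dict[tuple[int, int], list[str]]]:
    """Remove analyzer drift using the empty-chamber segments.

    A drift curve is fit through the per-baseline-segment median gas
    values (linear interpolation by default) and subtracted.  The O2
    deflection is negated and divided by 100 so that consumption gives a
    positive fractional dO2; CO2 is divided by 100.  Animal segments not
    bracketed by baseline segments get an extrapolation flag.

    Returns ``(delta_o2, delta_co2, segment_flags)`` with the deltas as
    full-length fractional arrays.
    """
    baselines = schedule.baseline_segments()
    if not baselines:
        raise ReductionDomainError("no baseline (channel 0) segments in schedule")

    t_anchor, o2_anchor, co2_anchor = [], [], []
    for seg in baselines:
        sl = _washout_slice(trace, seg, params.washout_s)
        if sl.start >= sl.stop:
            sl = segment_slice(trace, seg)
        t_anchor.append(float(np.median(trace.time_s[sl])))
        o2_anchor.append(float(np.median(trace.o2_pct[sl])))
        co2_anchor.append(float(np.median(trace.co2_pct[sl])))
    t_anchor = np.asarray(t_anchor)
    order = np.argsort(t_anchor)
    t_anchor = t_anchor[order]
    o2_anchor = np.asarray(o2_anchor)[order]
    co2_anchor = np.asarray(co2_anchor)[order]

    o2_drift = _drift_curve(t_anchor, o2_anchor, trace.time_s, params.baseline_mode)
    co2_drift = _drift_curve(t_anchor, co2_anchor, trace.time_s, params.baseline_mode)

    delta_o2 = -(trace.o2_pct - o2_drift) / 100.0
    delta_co2 = (trace.co2_pct - co2_drift) / 100.0

    flags: dict[tuple[int, int], list[str]] = {}
    for seg in schedule.animal_segments(include_short=True):
        seg_flags: list[str] = []
        mid = 0.5 * (seg.start_s + seg.end_s)
        if mid < t_anchor[0] or mid > t_anchor[-1]:
            seg_flags.append(FLAG_EXTRAPOLATED_BASELINE)
        if seg.short:
            seg_flags.append(FLAG_SHORT_SEGMENT)
        flags[(seg.channel, seg.repetition)] = seg_flags
    return delta_o2, delta_co2, flags


# ---------------------------------------------------------------------------
# Flow and VO2
# ---------------------------------------------------------------------------

def correct_flow(fr_ml_min, bp_kpa, wvp_kpa):
    """Water-vapor flow correction: FRd = FR * (BP - WVP) / BP."""
    fr = np.asarray(fr_ml_min, dtype=np.float64)
    bp = np.asarray(bp_kpa, dtype=np.float64)
    wvp = np.asarray(wvp_kpa, dtype=np.float64)
    if np.any(wvp < 0) or np.any(wvp >= bp):
        raise ReductionDomainError("require 0 <= WVP < BP")
    return fr * (bp - wvp) / bp


def compute_vo2(delta_o2, fr_d_ml_min, params: ReductionParams):
    """Oxygen consumption in ml h^-1 from fractional dO2 and corrected flow.

    With the excurrent stream scrubbed of H2O and CO2 before the O2 cell:
    ``FeO2 = fio2_ref - dO2`` and ``VO2 = 60 * FRd * dO2 / (1 - FeO2)``.
    """
    d = np.asarray(delta_o2, dtype=np.float64)
    fr_d = np.asarray(fr_d_ml_min, dtype=np.float64)
    if np.any(d >= params.fio2_ref):
        raise ReductionDomainError("delta_o2 must be < fio2_ref")
    fe_o2 = params.fio2_ref - d
    return fr_d * 60.0 * d / (1.0 - fe_o2)


# ---------------------------------------------------------------------------
# End-to-end trial reduction
# ---------------------------------------------------------------------------

def reduce_trial(
    trace: RespirometryTrace,
    schedule: ChannelSchedule | None = None,
    params: ReductionParams | None = None,
) -> list[Vo2Series]:
    """Raw trace -> one :class:`Vo2Series` per animal-channel repetition.

    Applies lag correction, baseline correction, the flow correction and
    the VO2 computation, then slices out each animal segment with the
    first ``washout_s`` seconds after the switch discarded.  QC flags from
    every stage are carried on the output series.
    """
    params = params or ReductionParams()
    if schedule is None:
        schedule = infer_schedule(trace)

    aligned, lag_report = correct_lag(trace, params)
    delta_o2, _delta_co2, seg_flags = baseline_correct(aligned, schedule, params)
    fr_d = correct_flow(aligned.fr_ml_min, aligned.bp_kpa, aligned.wvp_kpa)
    vo2 = compute_vo2(delta_o2, fr_d, params)

    out: list[Vo2Series] = []
    for seg in schedule.animal_segments(include_short=True):
        sl = _washout_slice(aligned, seg, params.washout_s)
        if sl.start >= sl.stop:
            continue
        flags = list(seg_flags.get((seg.channel, seg.repetition), []))
        flags.extend(sorted(set(lag_report.flags.values())))
        out.append(
            Vo2Series(
                channel=seg.channel,
                repetition=seg.repetition,
                time_s=aligned.time_s[sl],
                vo2_ml_h=vo2[sl],
                fr_d_ml_min=fr_d[sl],
                flags=flags,
            )
        )
    return out
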