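"""Activity screening and two-stage window search for per-trial RMR.

For each surviving repetition the search finds the 450-s interval with
the lowest VO2 standard deviation and, nested inside it, the 60-s
interval with the lowest mean.  The trial's RMR is the minimum of those
candidate means across repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from respicall.errors import InsufficientDataError
from respicall.reduction import Vo2Series

FLAG_TOO_SHORT = "repetition_shorter_than_stable_window"


@dataclass
class WindowSearchParams:
    """Window-search and activity-screening knobs.

    ``stride_s`` of ``None`` means one sample.  ``activity_jump_threshold``
    is the rejection multiple of the median absolute deviation (MAD) of
    the smoothed series' first differences; ``math.inf`` disables the
    screen.  ``qc_max_flagged_frac`` discards repetitions with more than
    that fraction of reduction-flagged samples.
    """

    stable_window_s: float = 450.0
    min_window_s: float = 60.0
    stride_s: float | None = None
    activity_jump_threshold: float = 6.0
    smooth_s: float = 5.0
    qc_max_flagged_frac: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.min_window_s <= self.stable_window_s:
            raise ValueError("require 0 < min_window_s <= stable_window_s")


@dataclass
class ScreenDecision:
    keep: bool
    reason: str
    jump_statistic: float


@dataclass
class CandidateWindow:
    """Winning nested window of one repetition."""

    repetition: int
    channel: int
    stable_start_s: float
    stable_end_s: float
    start_s: float
    end_s: float
    mean_vo2_ml_h: float


@dataclass
class TrialRmr:
    """One individual's RMR on one measurement day, with provenance."""

    individual_id: str
    date: object
    rmr_ml_o2_h: float
    repetition: int
    window_start_s: float
    window_end_s: float
    n_reps_used: int
    n_reps_discarded: int
    usable: bool = True


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="valid")


def screen_activity(rep: Vo2Series, params: WindowSearchParams) -> ScreenDecision:
    """Keep/discard a repetition based on sudden VO2 jumps.

    The statistic is the maximum absolute first difference of a
    ``smooth_s``-wide moving average, in units of the robust (MAD-based)
    scale of those differences.  Activity bursts produce step changes far
    above that scale; analyzer noise does not.
    """
    if rep.sample_flagged is not None:
        frac = float(np.mean(rep.sample_flagged))
        if frac > params.qc_max_flagged_frac:
            return ScreenDecision(False, f"qc_flagged_frac={frac:.3f}", np.inf)

    width = max(1, int(round(params.smooth_s / rep.dt)))
    smoothed = _moving_average(rep.vo2_ml_h, width)
    if len(smoothed) < 3:
        return ScreenDecision(True, "too_short_to_screen", 0.0)
    d = np.diff(smoothed)
    mad = np.median(np.abs(d - np.median(d))) * 1.4826
    peak = float(np.max(np.abs(d)))
    if peak == 0.0:
        return ScreenDecision(True, "flat", 0.0)
    stat = peak / mad if mad > 0 else np.inf
    if stat > params.activity_jump_threshold:
        return ScreenDecision(False, f"jump_statistic={stat:.2f}", stat)
    return ScreenDecision(True, "ok", stat)


def find_candidate(
    rep: Vo2Series, params: WindowSearchParams
) -> CandidateWindow | None:
    """Two-stage nested window search on one repetition.

    Stage 1 slides a ``stable_window_s`` window (stride ``stride_s``) and
    keeps the one with minimum standard deviation; stage 2 slides a
    ``min_window_s`` window inside it and keeps the minimum mean.  Ties
    break to the earliest start.  Returns ``None`` (caller flags the
    repetition) when the series is shorter than the stable window.
    """
    dt = rep.dt
    w1 = int(round(params.stable_window_s / dt))
    w2 = int(round(params.min_window_s / dt))
    stride = max(1, int(round((params.stride_s or dt) / dt)))
    x = rep.vo2_ml_h
    if len(x) < w1:
        return None

    views1 = sliding_window_view(x, w1)[::stride]
    sds = views1.std(axis=1)
    i1 = int(np.argmin(sds)) * stride  # argmin takes the first minimum

    inner = x[i1 : i1 + w1]
    views2 = sliding_window_view(inner, w2)[::stride]
    means = views2.mean(axis=1)
    i2 = i1 + int(np.argmin(means)) * stride

    return CandidateWindow(
        repetition=rep.repetition,
        channel=rep.channel,
        stable_start_s=float(rep.time_s[i1]),
        stable_end_s=float(rep.time_s[i1]) + w1 * dt,
        start_s=float(rep.time_s[i2]),
        end_s=float(rep.time_s[i2]) + w2 * dt,
        mean_vo2_ml_h=float(np.mean(x[i2 : i2 + w2])),
    )


def extract_trial_rmr(
    reps: list[Vo2Series],
    params: WindowSearchParams | None = None,
    individual_id: str = "",
    date: object = None,
) -> TrialRmr:
    """Minimum candidate mean across activity-screened repetitions.

    A trial with zero surviving repetitions (all active, flagged, or too
    short) is returned with ``usable=False`` and a NaN RMR rather than
    raising, mirroring whole-trial removal upstream.
    """
    params = params or WindowSearchParams()
    if not reps:
        raise InsufficientDataError("no repetitions supplied")

    candidates: list[CandidateWindow] = []
    n_discarded = 0
    for rep in reps:
        decision = screen_activity(rep, params)
        if not decision.keep:
            n_discarded += 1
            continue
        cand = find_candidate(rep, params)
        if cand is None:
            n_discarded += 1
            continue
        candidates.append(cand)

    if not candidates:
        return TrialRmr(
            individual_id=individual_id,
            date=date,
            rmr_ml_o2_h=float("nan"),
            repetition=-1,
            window_start_s=float("nan"),
            window_end_s=float("nan"),
            n_reps_used=0,
            n_reps_discarded=n_discarded,
            usable=False,
        )

    best = min(candidates, key=lambda c: c.mean_vo2_ml_h)
    return TrialRmr(
        individual_id=individual_id,
        date=date,
        rmr_ml_o2_h=best.mean_vo2_ml_h,
        repetition=best.repetition,
        window_start_s=best.start_s,
        window_end_s=best.end_s,
        n_reps_used=len(candidates),
        n_reps_discarded=n_discarded,
    )
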