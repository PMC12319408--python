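"""Synthetic cohorts, respirometry traces and call datasets with known truth.

Every generator takes an explicit :class:`numpy.random.Generator` (or a
seed) and is fully deterministic given it.  Default parameters are
anchored to the published summary values of the study system (mean RMR
~0.92 ml O2 h^-1, a -0.01 ml h^-1 day^-1 seasonal decline, mass slope
0.18 ml h^-1 g^-1, adjusted repeatability 0.4, ~100 ml min^-1 flow,
15-min multiplexer dwells, 30 calls per recording) so that synthetic
runs are numerically comparable to the field study; they are anchors for
realism, not a reconstruction of the real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from respicall.errors import ReductionDomainError
from respicall.model import RespirometryTrace

# ---------------------------------------------------------------------------
# Cohort generator
# ---------------------------------------------------------------------------


@dataclass
class CohortParams:
    """Generative model for individuals and their true per-trial RMR.

    True RMR for individual i on trial t:

        rmr = intercept + mass_slope * mass_i + day_slope * day_it
              + year_offset_2024 * [year_i == 2024] + b_i + e_it

    with ``b_i ~ N(0, ind_sd^2)`` and ``e_it ~ N(0, resid_sd^2)``.  The
    default variance split gives a true adjusted repeatability of 0.4.
    """

    n_individuals: int = 100
    mass_mean_g: float = 5.1
    mass_sd_g: float = 1.0
    rmr_intercept: float = 1.854
    mass_slope: float = 0.18
    day_slope: float = -0.01
    year_offset_2024: float = -0.24
    ind_sd: float = 0.14819581787688085  # sqrt(0.4 * 0.0549)
    resid_sd: float = 0.18149380705505542  # sqrt(0.6 * 0.0549)
    recapture_fracs: tuple[float, float, float] = (0.71, 0.21, 0.08)
    day_range: tuple[int, int] = (130, 200)
    gap_range: tuple[int, int] = (3, 45)
    frac_2024: float = 0.5
    temp_mean_c: float = 21.7
    temp_sd_c: float = 2.7
    temp_range_c: tuple[float, float] = (14.8, 29.8)
    rmr_floor: float = 0.05
    n_ponds: int = 7

    def __post_init__(self) -> None:
        if self.ind_sd < 0 or self.resid_sd < 0:
            raise ValueError("SDs must be >= 0")
        if abs(sum(self.recapture_fracs) - 1.0) > 1e-9:
            raise ValueError("recapture fractions must sum to 1")

    @property
    def true_repeatability(self) -> float:
        tot = self.ind_sd**2 + self.resid_sd**2
        return self.ind_sd**2 / tot if tot > 0 else 0.0

    def with_repeatability(self, r: float, total_sd: float | None = None) -> "CohortParams":
        """Same params with the ind/resid variance split set to give R=r."""
        tot = (total_sd or np.hypot(self.ind_sd, self.resid_sd)) ** 2
        return replace(
            self, ind_sd=float(np.sqrt(r * tot)), resid_sd=float(np.sqrt((1 - r) * tot))
        )


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_cohort(
    params: CohortParams, rng=0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a cohort; returns ``(individuals, trials)``.

    ``trials`` carries one row per measurement day with the latent
    ``true_rmr_ml_o2_h`` alongside the observable covariates (year,
    calendar day, mass, calling-night temperature).
    """
    rng = _rng(rng)
    n = params.n_individuals
    ids = np.array([f"frog{i:03d}" for i in range(n)])
    mass = np.maximum(rng.normal(params.mass_mean_g, params.mass_sd_g, n), 1.0)
    year = np.where(rng.random(n) < params.frac_2024, 2024, 2023)
    pond = np.array([f"pond{p}" for p in rng.integers(0, params.n_ponds, n)])
    b_ind = rng.normal(0.0, params.ind_sd, n)
    n_trials = rng.choice([1, 2, 3], size=n, p=list(params.recapture_fracs))

    individuals = pd.DataFrame(
        {
            "individual_id": ids,
            "mass_g": mass,
            "year": year,
            "pond": pond,
            "n_trials": n_trials,
            "true_intercept_dev": b_ind,
        }
    )

    rows = []
    lo, hi = params.day_range
    for i in range(n):
        day = int(rng.integers(lo, hi + 1))
        for t in range(n_trials[i]):
            if t > 0:
                day += int(rng.integers(params.gap_range[0], params.gap_range[1] + 1))
            temp = float(
                np.clip(
                    rng.normal(params.temp_mean_c, params.temp_sd_c),
                    *params.temp_range_c,
                )
            )
            true = (
                params.rmr_intercept
                + params.mass_slope * mass[i]
                + params.day_slope * day
                + (params.year_offset_2024 if year[i] == 2024 else 0.0)
                + b_ind[i]
                + rng.normal(0.0, params.resid_sd)
            )
            rows.append(
                {
                    "individual_id": ids[i],
                    "trial_idx": t + 1,
                    "year": int(year[i]),
                    "calendar_day": day,
                    "mass_g": float(mass[i]),
                    "temp_c": temp,
                    "pond": pond[i],
                    "true_rmr_ml_o2_h": max(float(true), params.rmr_floor),
                }
            )
    trials = pd.DataFrame(rows)
    return individuals, trials


# ---------------------------------------------------------------------------
# Trace generator
# ---------------------------------------------------------------------------


@dataclass
class TraceSimParams:
    """Physical model of one multiplexed recording day.

    The O2 deflection for a chamber is the exact inverse of the flow and
    oxygen-consumption equations, so a noiseless trace reduces back to
    the injected true VO2 to machine precision.  Drift, analyzer noise,
    an injected gas-channel lag and multiplicative activity bursts are
    layered on top; burst intervals are returned as labels.
    """

    fs_hz: float = 1.0
    dwell_s: float = 900.0
    n_cycles: int = 3
    flow_ml_min: float = 100.0
    o2_baseline_pct: float = 20.95
    co2_baseline_pct: float = 0.005
    bp_kpa: float = 101.3
    wvp_kpa: float = 2.0
    wvp_chamber_offset_kpa: float = 0.05
    o2_noise_sd_pct: float = 0.00027  # ~0.02 ml h^-1 VO2-equivalent at 100 ml min^-1
    co2_noise_sd_pct: float = 0.0003
    wvp_noise_sd_kpa: float = 0.001
    o2_drift_pct_per_h: float = -0.02
    co2_drift_pct_per_h: float = 0.004
    lag_s: float = 3.0
    burst_prob_per_rep: float = 0.1
    burst_amp: float = 3.0
    burst_dur_s: float = 120.0
    washout_tau_s: float = 0.0  # 0 = instantaneous chamber step

    @property
    def fio2_ref(self) -> float:
        return self.o2_baseline_pct / 100.0


@dataclass
class TraceSimResult:
    trace: RespirometryTrace
    burst_reps: dict[tuple[int, int], bool] = field(default_factory=dict)
    injected_lag_samples: int = 0
    true_vo2_by_channel: dict[int, float] = field(default_factory=dict)


def invert_vo2(true_vo2_ml_h: float, fr_d_ml_min: float, fio2_ref: float) -> float:
    """Fractional dO2 producing ``true_vo2_ml_h`` at corrected flow FRd."""
    denom = 60.0 * fr_d_ml_min - true_vo2_ml_h
    if denom <= 0:
        raise ReductionDomainError("true VO2 too large for this flow")
    d = true_vo2_ml_h * (1.0 - fio2_ref) / denom
    if d >= fio2_ref:
        raise ReductionDomainError("true VO2 infeasible at this fio2_ref")
    return d


def simulate_trace(
    true_vo2_by_channel: dict[int, float],
    params: TraceSimParams | None = None,
    rng=0,
) -> TraceSimResult:
    """One full multiplexed recording day.

    The multiplexer visits the baseline chamber (channel 0) and then each
    animal chamber for ``dwell_s`` per cycle, for ``n_cycles`` cycles,
    and closes with a final baseline dwell.
    """
    params = params or TraceSimParams()
    rng = _rng(rng)
    channels = sorted(true_vo2_by_channel)
    if any(c <= 0 for c in channels):
        raise ValueError("animal channels must be positive integers")
    if any(v < 0 for v in true_vo2_by_channel.values()):
        raise ValueError("true VO2 must be >= 0")

    order: list[int] = []
    for _ in range(params.n_cycles):
        order.append(0)
        order.extend(channels)
    order.append(0)

    dt = 1.0 / params.fs_hz
    n_per = int(round(params.dwell_s * params.fs_hz))
    n_total = n_per * len(order)
    time_s = np.arange(n_total) * dt
    marker = np.repeat(order, n_per)

    fr = np.full(n_total, params.flow_ml_min)
    bp = np.full(n_total, params.bp_kpa)
    wvp = params.wvp_kpa + params.wvp_chamber_offset_kpa * (marker != 0)
    fr_d_nominal = params.flow_ml_min * (params.bp_kpa - params.wvp_kpa
                                         - params.wvp_chamber_offset_kpa) / params.bp_kpa

    # per-sample true VO2, with activity bursts on some repetitions
    vo2_true = np.zeros(n_total)
    rep_count = {c: 0 for c in channels}
    burst_reps: dict[tuple[int, int], bool] = {}
    for k, c in enumerate(order):
        if c == 0:
            continue
        rep_count[c] += 1
        sl = slice(k * n_per, (k + 1) * n_per)
        vo2_true[sl] = true_vo2_by_channel[c]
        burst = rng.random() < params.burst_prob_per_rep
        burst_reps[(c, rep_count[c])] = burst
        if burst:
            b_len = int(round(params.burst_dur_s * params.fs_hz))
            b0 = int(rng.integers(0, max(n_per - b_len, 1)))
            vo2_true[sl.start + b0 : min(sl.start + b0 + b_len, sl.stop)] *= params.burst_amp

    # exact inversion to a fractional O2 deflection
    delta = np.zeros(n_total)
    active = vo2_true > 0
    if np.any(active):
        vals = vo2_true[active]
        denom = 60.0 * fr_d_nominal - vals
        if np.any(denom <= 0):
            raise ReductionDomainError("true VO2 too large for this flow")
        d = vals * (1.0 - params.fio2_ref) / denom
        if np.any(d >= params.fio2_ref):
            raise ReductionDomainError("true VO2 infeasible at this fio2_ref")
        delta[active] = d
    if params.washout_tau_s > 0:
        # first-order analyzer/chamber response
        alpha = dt / (params.washout_tau_s + dt)
        out = np.empty_like(delta)
        acc = delta[0]
        for i, d in enumerate(delta):
            acc += alpha * (d - acc)
            out[i] = acc
        delta = out

    drift_o2 = params.o2_drift_pct_per_h * time_s / 3600.0
    drift_co2 = params.co2_drift_pct_per_h * time_s / 3600.0
    o2 = params.o2_baseline_pct + drift_o2 - 100.0 * delta
    co2 = params.co2_baseline_pct + drift_co2 + 80.0 * delta  # QC channel only

    lag = int(round(params.lag_s * params.fs_hz))
    if lag > 0:
        o2 = np.concatenate((np.full(lag, o2[0]), o2[:-lag]))
        co2 = np.concatenate((np.full(lag, co2[0]), co2[:-lag]))

    if params.o2_noise_sd_pct > 0:
        o2 = o2 + rng.normal(0.0, params.o2_noise_sd_pct, n_total)
    if params.co2_noise_sd_pct > 0:
        co2 = np.abs(co2 + rng.normal(0.0, params.co2_noise_sd_pct, n_total))
    if params.wvp_noise_sd_kpa > 0:
        wvp = wvp + rng.normal(0.0, params.wvp_noise_sd_kpa, n_total)

    trace = RespirometryTrace(
        time_s=time_s,
        o2_pct=o2,
        co2_pct=co2,
        wvp_kpa=wvp,
        bp_kpa=bp,
        fr_ml_min=fr,
        channel=marker,
    )
    return TraceSimResult(
        trace=trace,
        burst_reps=burst_reps,
        injected_lag_samples=lag,
        true_vo2_by_channel=dict(true_vo2_by_channel),
    )


def simulate_cohort_traces(
    trials: pd.DataFrame,
    params: TraceSimParams | None = None,
    rng=0,
    max_channels: int = 7,
):
    """Group trials into measurement days and simulate one trace per day.

    Trials sharing (year, calendar_day) are measured together, up to
    ``max_channels`` animal chambers per trace (channel 8 is the empty
    control, represented as marker 0).  Yields
    ``(TraceSimResult, assignment)`` with assignment mapping channel ->
    trials-row index.
    """
    params = params or TraceSimParams()
    rng = _rng(rng)
    out = []
    for (_, _), g in trials.groupby(["year", "calendar_day"], sort=True):
        idx = list(g.index)
        for chunk_start in range(0, len(idx), max_channels):
            chunk = idx[chunk_start : chunk_start + max_channels]
            assignment = {ch + 1: row for ch, row in enumerate(chunk)}
            true_vo2 = {
                ch: float(trials.at[row, "true_rmr_ml_o2_h"])
                for ch, row in assignment.items()
            }
            out.append((simulate_trace(true_vo2, params, rng), assignment))
    return out


# ---------------------------------------------------------------------------
# Call generator
# ---------------------------------------------------------------------------


@dataclass
class TraitModel:
    """Linear generative model for one call trait's per-recording mean."""

    intercept: float
    temp_slope: float
    day_slope: float
    mass_slope: float
    year_offset: float
    rmr_slope: float = 0.0
    ind_sd: float = 0.0
    resid_sd: float = 0.0

    def mean(self, temp, day, mass, is_2024, rmr) -> float:
        return (
            self.intercept
            + self.temp_slope * temp
            + self.day_slope * day
            + self.mass_slope * mass
            + (self.year_offset if is_2024 else 0.0)
            + self.rmr_slope * rmr
        )


def default_trait_models() -> dict[str, TraitModel]:
    """Covariate slopes anchored to the published call-trait models; zero
    RMR effect by default (the null generating model)."""
    return {
        "call_duration_s": TraitModel(1.427, -0.03, -0.001, -0.009, 0.07,
                                      ind_sd=0.06, resid_sd=0.05),
        "pulse_number": TraitModel(49.24, -0.07, -0.10, -0.49, 2.56,
                                   ind_sd=3.0, resid_sd=2.5),
        "dominant_frequency_hz": TraitModel(2291.3, 1.63, 2.39, -63.96, 10.32,
                                            ind_sd=80.0, resid_sd=60.0),
        "call_rate_per_s": TraitModel(-0.069, 0.010, 0.0001, 0.006, -0.03,
                                      ind_sd=0.025, resid_sd=0.02),
    }


@dataclass
class CallSimParams:
    """Mixed-effects generative model for call recordings.

    Call effort is not simulated directly: it emerges as duration x rate
    from the synthesized event table, exactly as the feature extractor
    computes it.
    """

    traits: dict[str, TraitModel] = field(default_factory=default_trait_models)
    calls_per_recording: int = 30
    call_duration_jitter_s: float = 0.02
    call_interval_jitter: float = 0.05  # lognormal sigma on onset intervals
    pulse_count_jitter: float = 1.0
    domfreq_jitter_hz: float = 15.0
    min_rate_per_s: float = 0.02
    min_duration_s: float = 0.05
    # audio synthesis
    audio_fs_hz: int = 44100
    audio_snr_db: float = 20.0

    def __post_init__(self) -> None:
        if self.calls_per_recording < 2:
            raise ValueError("need >= 2 calls per recording")


def simulate_calls(
    trials: pd.DataFrame,
    individuals: pd.DataFrame,
    params: CallSimParams | None = None,
    rng=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthesize call event tables for each trial's calling night.

    Returns ``(events, recordings)``: per-call events in the canonical
    table format, and per-recording metadata (individual, temperature,
    covariates, true trait means) keyed by ``recording_id``.
    """
    params = params or CallSimParams()
    rng = _rng(rng)
    ind_dev = {
        ind: {t: rng.normal(0.0, m.ind_sd) for t, m in params.traits.items()}
        for ind in individuals["individual_id"]
    }

    events_rows = []
    rec_rows = []
    for row in trials.itertuples():
        rid = f"rec_{row.individual_id}_{row.trial_idx}"
        is_2024 = row.year == 2024
        rmr = row.true_rmr_ml_o2_h
        rec_traits = {}
        for t, m in params.traits.items():
            val = (
                m.mean(row.temp_c, row.calendar_day, row.mass_g, is_2024, rmr)
                + ind_dev[row.individual_id][t]
                + rng.normal(0.0, m.resid_sd)
            )
            rec_traits[t] = val
        rate = max(rec_traits["call_rate_per_s"], params.min_rate_per_s)
        duration = max(rec_traits["call_duration_s"], params.min_duration_s)

        onset = 0.0
        for k in range(params.calls_per_recording):
            interval = (1.0 / rate) * float(
                rng.lognormal(0.0, params.call_interval_jitter)
            )
            dur_k = max(
                duration + rng.normal(0.0, params.call_duration_jitter_s),
                params.min_duration_s,
            )
            dur_k = min(dur_k, 0.9 * interval)
            pulses = max(
                1,
                int(round(rec_traits["pulse_number"]
                          + rng.normal(0.0, params.pulse_count_jitter))),
            )
            domf = max(
                rec_traits["dominant_frequency_hz"]
                + rng.normal(0.0, params.domfreq_jitter_hz),
                100.0,
            )
            events_rows.append(
                {
                    "recording_id": rid,
                    "call_idx": k,
                    "onset_s": onset,
                    "offset_s": onset + dur_k,
                    "pulse_count": pulses,
                    "domfreq_hz": domf,
                    "observer": "sim",
                }
            )
            onset += interval

        rec_rows.append(
            {
                "recording_id": rid,
                "individual_id": row.individual_id,
                "trial_idx": row.trial_idx,
                "year": row.year,
                "calendar_day": row.calendar_day,
                "mass_g": row.mass_g,
                "temp_c": row.temp_c,
                "true_rmr_ml_o2_h": rmr,
                **{f"true_{t}": v for t, v in rec_traits.items()},
            }
        )
    return pd.DataFrame(events_rows), pd.DataFrame(rec_rows)


def synthesize_call_audio(
    events: pd.DataFrame, params: CallSimParams | None = None, rng=0
) -> tuple[int, np.ndarray]:
    """Pulsatile audio consistent with one recording's event table.

    Each call is ``pulse_count`` raised-cosine amplitude pulses spread
    evenly over the call duration, on the call's dominant-frequency
    carrier, in white noise at ``audio_snr_db``.
    """
    params = params or CallSimParams()
    rng = _rng(rng)
    fs = params.audio_fs_hz
    total_s = float(events["offset_s"].max()) + 1.0
    n = int(total_s * fs)
    x = np.zeros(n)
    for ev in events.itertuples():
        dur = ev.offset_s - ev.onset_s
        n_p = int(ev.pulse_count)
        pulse_len = dur / n_p
        n_pulse = max(int(pulse_len * fs), 8)
        window = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n_pulse) / n_pulse))
        for k in range(n_p):
            start = int((ev.onset_s + k * pulse_len) * fs)
            tt = np.arange(n_pulse) / fs
            burst = window * np.sin(2.0 * np.pi * ev.domfreq_hz * tt)
            end = min(start + n_pulse, n)
            x[start:end] += burst[: end - start]
    rms_signal = np.sqrt(np.mean(x[x != 0] ** 2)) if np.any(x != 0) else 1.0
    noise_sd = rms_signal / (10.0 ** (params.audio_snr_db / 20.0))
    x = x + rng.normal(0.0, noise_sd, n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / (1.1 * peak)
    return fs, x
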