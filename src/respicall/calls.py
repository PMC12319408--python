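"""Call characteristics from call event tables (or, optionally, audio).

Five traits per call: duration, pulse number, dominant frequency, call
rate (reciprocal of the onset-to-onset interval to the next call; the
final call of a recording has no rate) and call effort (duration x rate,
the fraction of time spent signaling).  Per-recording values are the
means over calls; rate and effort means exclude the final call.

The event-table path is canonical.  ``extract_from_audio`` is a bespoke
envelope-threshold segmenter for synthesized or field WAV audio; it is
not a re-implementation of any particular GUI tool's measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from respicall.errors import InsufficientDataError, TraceFormatError

EVENT_COLUMNS = (
    "recording_id",
    "call_idx",
    "onset_s",
    "offset_s",
    "pulse_count",
    "domfreq_hz",
    "observer",
)


@dataclass(frozen=True)
class CallEvent:
    """One call in one recording, as measured by one observer."""

    recording_id: str
    call_idx: int
    onset_s: float
    offset_s: float
    pulse_count: int
    domfreq_hz: float
    observer: str = ""

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset_s must exceed onset_s")
        if self.pulse_count < 1:
            raise ValueError("pulse_count must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class RecordingFeatures:
    """Per-recording trait means joined to the calling-site temperature."""

    recording_id: str
    individual_id: str
    n_calls: int
    call_duration_s: float
    pulse_number: float
    dominant_frequency_hz: float
    call_rate_per_s: float
    call_effort: float
    skin_temperature_c: float = float("nan")


def read_call_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "observer"]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    return df


def call_rate(onsets_s) -> np.ndarray:
    """Per-call rates 1 / (onset_{i+1} - onset_i); length n-1.

    Onsets must be strictly increasing; duplicates raise ``ValueError``.
    """
    onsets = np.asarray(onsets_s, dtype=float)
    if len(onsets) < 2:
        raise InsufficientDataError("call rate needs >= 2 calls")
    gaps = np.diff(onsets)
    if np.any(gaps <= 0):
        raise ValueError("onsets must be strictly increasing (no duplicates)")
    return 1.0 / gaps


def call_effort(duration_s, rate_per_s) -> np.ndarray:
    """Per-call effort = duration x rate (fraction of time calling)."""
    return np.asarray(duration_s, dtype=float) * np.asarray(rate_per_s, dtype=float)


def recording_features(
    events: pd.DataFrame,
    individual_id: str = "",
    skin_temperature_c: float = float("nan"),
) -> RecordingFeatures:
    """Trait means for one recording's event table.

    Row order does not matter; rates are recomputed from sorted onsets.
    """
    ev = events.sort_values("onset_s").reset_index(drop=True)
    if ev["onset_s"].duplicated().any():
        raise ValueError("duplicate call onsets")
    durations = (ev["offset_s"] - ev["onset_s"]).to_numpy(dtype=float)
    rates = call_rate(ev["onset_s"].to_numpy())
    efforts = call_effort(durations[:-1], rates)
    return RecordingFeatures(
        recording_id=str(ev["recording_id"].iloc[0]),
        individual_id=individual_id,
        n_calls=len(ev),
        call_duration_s=float(durations.mean()),
        pulse_number=float(ev["pulse_count"].mean()),
        dominant_frequency_hz=float(ev["domfreq_hz"].mean()),
        call_rate_per_s=float(rates.mean()),
        call_effort=float(efforts.mean()),
        skin_temperature_c=skin_temperature_c,
    )


def features_table(events: pd.DataFrame, metadata: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-recording feature rows for a multi-recording event table.

    ``metadata``, if given, is joined on ``recording_id`` and may carry
    ``individual_id`` and ``temp_c``.
    """
    rows = []
    for rid, g in events.groupby("recording_id", sort=False):
        ind, temp = "", float("nan")
        if metadata is not None:
            m = metadata.loc[metadata["recording_id"] == rid]
            if len(m):
                ind = str(m["individual_id"].iloc[0])
                temp = float(m["temp_c"].iloc[0]) if "temp_c" in m else float("nan")
        rf = recording_features(g, individual_id=ind, skin_temperature_c=temp)
        rows.append(vars(rf))
    df = pd.DataFrame(rows)
    return df.rename(columns={"skin_temperature_c": "temp_c"})


def interobserver_reliability(a, b) -> tuple[float, float]:
    """Pearson r and OLS slope of observer B's call measurements on A's.

    The slope's ideal value is 1; zero variance in A leaves it undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise InsufficientDataError("need matched vectors with n >= 3")
    if np.var(a) == 0:
        raise ZeroDivisionError("zero variance in observer A; slope undefined")
    r = float(np.corrcoef(a, b)[0, 1])
    slope = float(np.cov(a, b, ddof=1)[0, 1] / np.var(a, ddof=1))
    return r, slope


# ---------------------------------------------------------------------------
# Optional audio path
# ---------------------------------------------------------------------------

@dataclass
class AudioDetectionParams:
    envelope_lowpass_hz: float = 40.0
    onset_threshold: float = 6.0   # multiple of the noise floor, call on
    offset_threshold: float = 3.0  # hysteresis, call off
    min_gap_s: float = 0.2
    min_call_s: float = 0.05
    pulse_min_prominence: float = 0.25  # fraction of in-call envelope peak
    welch_nperseg: int = 2048


def _envelope(x: np.ndarray, fs: float, lowpass_hz: float) -> np.ndarray:
    sos = signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.abs(x))


def extract_from_audio(
    wav, params: AudioDetectionParams | None = None
) -> pd.DataFrame:
    """Segment calls from audio and measure the per-call traits.

    ``wav`` is a path to a RIFF WAV file or an ``(fs, samples)`` tuple;
    multi-channel audio uses the first channel.  Calls are found by
    hysteresis thresholding of a smoothed amplitude envelope relative to
    the noise floor (envelope median); pulses are counted as prominent
    envelope peaks within the call; dominant frequency is the argmax of
    the call's Welch power spectrum.  Silence yields an empty table.
    """
    params = params or AudioDetectionParams()
    if isinstance(wav, tuple):
        fs, x = wav
    else:
        fs, x = wavfile.read(wav)
    x = np.asarray(x)
    if x.ndim > 1:
        x = x[:, 0]
    x = x.astype(np.float64)
    if x.dtype.kind != "f" or np.max(np.abs(x)) > 1.5:
        peak = np.max(np.abs(x))
        if peak > 0:
            x = x / peak

    env = _envelope(x, fs, params.envelope_lowpass_hz)
    floor = np.median(env)
    if floor <= 0:
        floor = np.mean(env) or 1.0
    hi, lo = params.onset_threshold * floor, params.offset_threshold * floor
    if not np.any(env > hi):
        return pd.DataFrame(columns=list(EVENT_COLUMNS))

    # hysteresis segmentation
    above_hi = env > hi
    above_lo = env > lo
    calls: list[tuple[int, int]] = []
    i = 0
    n = len(env)
    while i < n:
        if above_hi[i]:
            j0 = i
            while j0 > 0 and above_lo[j0 - 1]:
                j0 -= 1
            j1 = i
            while j1 < n and above_lo[j1]:
                j1 += 1
            calls.append((j0, j1))
            i = j1
        else:
            i += 1

    # merge segments separated by less than min_gap_s
    min_gap = int(params.min_gap_s * fs)
    merged: list[list[int]] = []
    for j0, j1 in calls:
        if merged and j0 - merged[-1][1] < min_gap:
            merged[-1][1] = j1
        else:
            merged.append([j0, j1])

    rows = []
    idx = 0
    for j0, j1 in merged:
        if (j1 - j0) / fs < params.min_call_s:
            continue
        seg_env = env[j0:j1]
        prominence = params.pulse_min_prominence * seg_env.max()
        peaks, _ = signal.find_peaks(seg_env, prominence=prominence)
        pulse_count = max(len(peaks), 1)
        seg = x[j0:j1]
        nper = min(params.welch_nperseg, len(seg))
        freqs, psd = signal.welch(seg, fs=fs, nperseg=nper)
        rows.append(
            {
                "recording_id": "audio",
                "call_idx": idx,
                "onset_s": j0 / fs,
                "offset_s": j1 / fs,
                "pulse_count": pulse_count,
                "domfreq_hz": float(freqs[np.argmax(psd)]),
                "observer": "auto",
            }
        )
        idx += 1
    return pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
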