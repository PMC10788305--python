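"""Slow (11 Hz) and fast (15 Hz) sleep-spindle detection.

Detection uses the amplitude envelope of a 7-cycle complex Morlet
wavelet transform, temporally smoothed with a 0.1-s centered moving
average, thresholded relative to the channel's mean envelope over all
retained N2 samples:

* an interval must exceed 2x the mean for at least 0.5 s and contain a
  sub-interval exceeding 4.5x the mean for at least 0.3 s;
* intervals longer than 3 s are rejected;
* consecutive intervals within 0.5 s are merged, unless the merged
  spindle would exceed 3 s.

Candidates then pass a band-ratio quality check: an event is discarded
if the relative increase (event window vs. stage baseline) in delta,
theta or beta activity exceeds the relative increase in spindle-band
activity.  Retained events are summarized by density (per retained
stage minute), amplitude (envelope peak, µV), duration, observed
frequency (mean instantaneous frequency) and chirp (last-half minus
first-half frequency of the event, from a quadratic phase model;
negative = intra-spindle deceleration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .hypnogram import EPOCH_SECONDS
from .preprocess import EpochedRecording, bandpass_filter

#: center frequencies of the two spindle classes (Hz)
CLASS_FC = {"slow": 11.0, "fast": 15.0}

#: non-spindle bands used by the quality check (Hz)
QC_BANDS = {"delta": (1.0, 4.0), "theta": (4.0, 8.0), "beta": (15.0, 30.0)}


@dataclass
class SpindleThresholds:
    core_factor: float = 4.5     # x mean envelope
    core_min_s: float = 0.3
    extent_factor: float = 2.0   # x mean envelope
    extent_min_s: float = 0.5
    max_duration_s: float = 3.0
    merge_gap_s: float = 0.5
    smooth_s: float = 0.1
    n_cycles: float = 7.0


def morlet_wavelet(fc: float, fs: float, n_cycles: float = 7.0) -> np.ndarray:
    """Complex Morlet wavelet normalized to unit envelope gain.

    The Gaussian envelope has SD ``n_cycles / (2*pi*fc)`` seconds and
    the wavelet is scaled so that convolution with a unit-amplitude
    sinusoid at ``fc`` yields an envelope of 1.
    """
    sigma_t = n_cycles / (2.0 * np.pi * fc)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-(t**2) / (2.0 * sigma_t**2))
    w = gauss * np.exp(2j * np.pi * fc * t)
    return w / (gauss.sum() / 2.0)


def cwt_envelope(signal: np.ndarray, fs: float, fc: float,
                 n_cycles: float = 7.0, smooth_s: float = 0.1) -> np.ndarray:
    """Smoothed magnitude of the complex Morlet transform at ``fc``.

    A unit-amplitude sinusoid at ``fc`` maps to an envelope of ~1, so
    the envelope reads in µV.
    """
    signal = np.asarray(signal, dtype=float)
    w = morlet_wavelet(fc, fs, n_cycles)
    if signal.size < len(w):
        raise ValueError(
            f"signal too short for a {n_cycles}-cycle wavelet at {fc} Hz")
    coef = sps.fftconvolve(signal, w, mode="same")
    env = np.abs(coef)
    n_sm = max(1, int(round(smooth_s * fs)))
    return uniform_filter1d(env, n_sm, mode="nearest")


def _runs_above(x: np.ndarray, thr: float) -> list[tuple[int, int]]:
    """Maximal half-open sample runs where x > thr."""
    above = x > thr
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        stops.append(len(x))
    return list(zip(starts, stops))


def detect_spindles(envelope: np.ndarray, fs: float,
                    thresholds: SpindleThresholds | None = None,
                    baseline_mean: float | None = None) -> list[tuple[int, int]]:
    """Dual-threshold interval detection on a smoothed envelope.

    ``baseline_mean`` defaults to the mean of the supplied envelope
    (i.e. the envelope should cover all retained stage samples for the
    channel).  Returns half-open sample intervals.
    """
    th = thresholds or SpindleThresholds()
    mean_env = float(np.mean(envelope)) if baseline_mean is None else baseline_mean
    if mean_env <= 0:
        raise ValueError("degenerate input: zero-mean envelope")
    n_core = int(round(th.core_min_s * fs))
    n_ext = int(round(th.extent_min_s * fs))
    n_max = int(round(th.max_duration_s * fs))
    n_gap = int(round(th.merge_gap_s * fs))

    candidates = []
    for a, b in _runs_above(envelope, th.extent_factor * mean_env):
        if b - a < n_ext:
            continue
        core = _runs_above(envelope[a:b], th.core_factor * mean_env)
        if any(cb - ca >= n_core for ca, cb in core):
            candidates.append((a, b))

    candidates = [(a, b) for a, b in candidates if b - a <= n_max]

    merged: list[tuple[int, int]] = []
    for a, b in candidates:
        if merged and a - merged[-1][1] < n_gap and b - merged[-1][0] <= n_max:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


@dataclass
class SpindleEvent:
    spindle_class: str
    channel: str
    start_s: float
    stop_s: float
    peak_time_s: float
    amplitude_uv: float
    duration_s: float
    frequency_hz: float
    chirp_hz: float
    qc_pass: bool = True
    qc_reason: str = ""


def _instantaneous_frequency(x: np.ndarray, fs: float) -> np.ndarray:
    phase = np.unwrap(np.angle(sps.hilbert(x)))
    return np.diff(phase) * fs / (2.0 * np.pi)


def _trough_support(env: np.ndarray, a: int, b: int,
                    max_ext: int) -> tuple[int, int]:
    """Extend a detected interval outward to the nearest envelope troughs.

    The dual-threshold interval covers only the event core; the
    envelope minima on either side approximate the event's full
    support, which morphology estimates (chirp in particular) need.
    """
    a0, b0 = a, b
    while a > 0 and a0 - a < max_ext and env[a - 1] < env[a]:
        a -= 1
    while b < len(env) - 1 and b - b0 < max_ext and env[b] > env[b + 1]:
        b += 1
    return a, b


def _event_freq_chirp(phase: np.ndarray, env: np.ndarray, fs: float,
                      a: int, b: int, support: tuple[int, int]) -> tuple[float, float]:
    """Frequency and chirp of one event by quadratic phase modelling.

    An envelope²-weighted quadratic is fit to the unwrapped Hilbert
    phase over the detected interval (where SNR is high); its curvature
    gives the linear chirp rate (Hz/s), which scaled by half the
    trough-to-trough support duration yields the last-half minus
    first-half frequency difference of the full event.  The fitted
    slope at the interval midpoint gives the observed frequency.
    Fitting the phase rather than its derivative avoids the noise
    amplification of per-sample instantaneous-frequency estimates.
    """
    if b - a < 8:
        return np.nan, np.nan
    ph = phase[a:b]
    w = env[a:b] ** 2
    w = w / w.sum()
    t = np.arange(b - a) / fs
    X = np.column_stack([np.ones_like(t), t, t**2])
    XtW = X.T * w
    try:
        beta = np.linalg.solve(XtW @ X, XtW @ ph)
    except np.linalg.LinAlgError:
        return np.nan, np.nan
    rate = beta[2] / np.pi                      # dF/dt, Hz/s
    freq = (beta[1] + 2.0 * beta[2] * t.mean()) / (2.0 * np.pi)
    duration = (support[1] - support[0]) / fs
    return float(freq), float(rate * duration / 2.0)


def spindle_qc(signal: np.ndarray, fs: float, fc: float,
               intervals: list[tuple[int, int]]) -> list[tuple[bool, str]]:
    """Band-ratio quality check against the stage baseline.

    For each event window the ratio (event-band variance / whole-signal
    band variance) is computed in delta, theta, beta and the spindle
    band (fc +/- 2 Hz); the event fails when any non-spindle ratio
    strictly exceeds the spindle ratio.
    """
    bands = dict(QC_BANDS)
    bands["spindle"] = (fc - 2.0, fc + 2.0)
    filtered = {name: bandpass_filter(signal, fs, lo, hi)
                for name, (lo, hi) in bands.items()}
    base = {name: np.var(x) for name, x in filtered.items()}
    out = []
    for a, b in intervals:
        ratios = {name: (np.var(filtered[name][a:b]) / base[name]
                         if base[name] > 0 else 0.0)
                  for name in bands}
        worst = max((n for n in QC_BANDS), key=lambda n: ratios[n])
        if ratios[worst] > ratios["spindle"]:
            out.append((False, f"band_ratio_{worst}"))
        else:
            out.append((True, ""))
    return out


def detect_channel_spindles(epoched: EpochedRecording, channel: str,
                            spindle_class: str, stage: str = "N2",
                            thresholds: SpindleThresholds | None = None,
                            ) -> list[SpindleEvent]:
    """Run the full detector for one channel and spindle class.

    Operates on the concatenation of retained stage epochs (the
    threshold baseline is the mean envelope over those samples) and
    maps events back to record time.  Events whose span straddles
    non-contiguous epochs are dropped.
    """
    th = thresholds or SpindleThresholds()
    fc = CLASS_FC[spindle_class]
    fs = epoched.recording.fs
    x, eps = epoched.concatenate(stage, channel)
    if x.size == 0:
        return []
    env = cwt_envelope(x, fs, fc, th.n_cycles, th.smooth_s)
    intervals = detect_spindles(env, fs, th)
    qc = spindle_qc(x, fs, fc, intervals)
    xf = bandpass_filter(x, fs, fc - 4.0, fc + 4.0)
    phase = np.unwrap(np.angle(sps.hilbert(xf)))

    n = int(round(EPOCH_SECONDS * fs))

    def to_record_time(sample: int) -> float:
        e = eps[min(sample // n, len(eps) - 1)]
        return e * EPOCH_SECONDS + (sample % n) / fs

    events = []
    for (a, b), (ok, reason) in zip(intervals, qc):
        start, stop = to_record_time(a), to_record_time(b - 1) + 1.0 / fs
        if abs((stop - start) - (b - a) / fs) > 1.5 / fs:
            continue  # straddles a gap between non-adjacent epochs
        peak = a + int(np.argmax(env[a:b]))
        support = _trough_support(env, a, b, max_ext=int(0.5 * fs))
        freq, chirp = _event_freq_chirp(phase, env, fs, a, b, support)
        events.append(SpindleEvent(
            spindle_class=spindle_class, channel=channel,
            start_s=start, stop_s=stop,
            peak_time_s=to_record_time(peak),
            amplitude_uv=float(env[a:b].max()),
            duration_s=(b - a) / fs,
            frequency_hz=freq, chirp_hz=chirp,
            qc_pass=ok, qc_reason=reason))
    return events


def spindle_metrics(events: list[SpindleEvent],
                    retained_minutes: float) -> dict:
    """Density and morphology summary over QC-passed events."""
    keep = [e for e in events if e.qc_pass]
    n = len(keep)
    out = {"n_events": n,
           "density": n / retained_minutes if retained_minutes > 0 else np.nan}
    for name, attr in (("amplitude", "amplitude_uv"), ("duration", "duration_s"),
                       ("frequency", "frequency_hz"), ("chirp", "chirp_hz")):
        vals = np.array([getattr(e, attr) for e in keep], dtype=float)
        out[name] = float(np.nanmean(vals)) if n else np.nan
    return out


def events_frame(events: list[SpindleEvent]) -> pd.DataFrame:
    cols = ["spindle_class", "channel", "start_s", "stop_s", "peak_time_s",
            "amplitude_uv", "duration_s", "frequency_hz", "chirp_hz",
            "qc_pass", "qc_reason"]
    return pd.DataFrame([e.__dict__ for e in events], columns=cols)
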