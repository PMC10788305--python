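"""Slow-oscillation (SO) detection by zero crossings in the 0.5-4 Hz band.

A candidate SO is anchored at a positive-to-negative zero crossing
(``down_zc``): the following negative half-wave (down_zc to the next
negative-to-positive crossing ``up_zc``) must last 0.3-1.5 s, and the
positive half-wave (up_zc to the subsequent positive-to-negative
crossing ``end_zc``) at most 1 s.

Amplitude thresholds come in two modes:

* relative (default): negative-peak magnitude and peak-to-peak
  amplitude must each exceed twice the per-channel mean of those
  quantities over all temporal-criteria-passing candidates (two-pass
  detection, so the thresholds are computable before selection);
* absolute: negative peak below -40 µV and peak-to-peak above 75 µV
  (strict comparisons).

Relative mode is invariant under a global gain change; absolute mode is
equivariant.  The two modes can disagree on age trends when SO
amplitude declines with age: a shrinking signal lowers the relative
threshold (detecting relatively more events) while pushing events below
a fixed absolute cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hypnogram import EPOCH_SECONDS
from .preprocess import EpochedRecording, bandpass_filter, SO_BAND


@dataclass
class SOThresholds:
    mode: str = "relative"          # "relative" | "absolute"
    relative_factor: float = 2.0
    abs_neg_uv: float = 40.0        # negative peak must be below -abs_neg_uv
    abs_p2p_uv: float = 75.0
    neg_min_s: float = 0.3
    neg_max_s: float = 1.5
    pos_max_s: float = 1.0

    def validate(self) -> None:
        if self.mode not in ("relative", "absolute"):
            raise ValueError(f"unknown SO threshold mode {self.mode!r}")


@dataclass
class SOEvent:
    channel: str
    down_zc_s: float
    up_zc_s: float
    end_zc_s: float
    neg_peak_time_s: float
    pos_peak_time_s: float
    neg_peak_uv: float      # < 0
    pos_peak_uv: float
    p2p_uv: float
    duration_s: float       # end_zc - down_zc (both half-waves)
    slope_uv_per_s: float   # p2p / (pos_peak_time - neg_peak_time)


def _zero_crossings(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of positive-to-negative and negative-to-positive crossings."""
    s = np.signbit(x)
    down = np.flatnonzero(~s[:-1] & s[1:]) + 1
    up = np.flatnonzero(s[:-1] & ~s[1:]) + 1
    return down, up


def _candidates(xf: np.ndarray, fs: float, th: SOThresholds):
    """Temporal-criteria-passing half-wave pairs on the filtered signal."""
    down, up = _zero_crossings(xf)
    out = []
    for d in down:
        u_idx = up[up > d]
        if not len(u_idx):
            break
        u = u_idx[0]
        neg_dur = (u - d) / fs
        if not (th.neg_min_s <= neg_dur <= th.neg_max_s):
            continue
        e_idx = down[down > u]
        if not len(e_idx):
            continue
        e = e_idx[0]
        pos_dur = (e - u) / fs
        if pos_dur > th.pos_max_s:
            continue
        neg_i = d + int(np.argmin(xf[d:u]))
        pos_i = u + int(np.argmax(xf[u:e]))
        out.append((d, u, e, neg_i, pos_i))
    return out


def detect_so(signal: np.ndarray, fs: float,
              thresholds: SOThresholds | None = None,
              prefiltered: bool = False) -> list[SOEvent]:
    """Detect SOs in a (concatenated) signal.

    ``signal`` should cover the retained stage samples for one channel;
    the 0.5-4 Hz zero-phase band-pass is applied internally unless
    ``prefiltered``.  Times in the returned events are seconds on the
    supplied timeline.
    """
    th = thresholds or SOThresholds()
    th.validate()
    if signal.size < 10 * fs:
        raise ValueError("need at least 10 s of usable signal")
    xf = signal if prefiltered else bandpass_filter(np.asarray(signal, float),
                                                    fs, *SO_BAND)
    cands = _candidates(xf, fs, th)
    if not cands:
        return []

    neg_peaks = np.array([xf[ni] for *_ignored, ni, _pi in cands])
    pos_peaks = np.array([xf[pi] for *_ignored, _ni, pi in cands])
    p2p = pos_peaks - neg_peaks

    if th.mode == "relative":
        neg_thr = th.relative_factor * np.mean(np.abs(neg_peaks))
        p2p_thr = th.relative_factor * np.mean(p2p)
        keep = (np.abs(neg_peaks) > neg_thr) & (p2p > p2p_thr)
    else:
        keep = (neg_peaks < -th.abs_neg_uv) & (p2p > th.abs_p2p_uv)

    events = []
    for k, (d, u, e, ni, pi) in enumerate(cands):
        if not keep[k]:
            continue
        dt = (pi - ni) / fs
        events.append(SOEvent(
            channel="", down_zc_s=d / fs, up_zc_s=u / fs, end_zc_s=e / fs,
            neg_peak_time_s=ni / fs, pos_peak_time_s=pi / fs,
            neg_peak_uv=float(neg_peaks[k]), pos_peak_uv=float(pos_peaks[k]),
            p2p_uv=float(p2p[k]), duration_s=(e - d) / fs,
            slope_uv_per_s=float(p2p[k] / dt) if dt > 0 else np.nan))
    return events


def detect_channel_so(epoched: EpochedRecording, channel: str,
                      stage: str = "N2",
                      thresholds: SOThresholds | None = None) -> list[SOEvent]:
    """Detect SOs on the concatenated retained epochs of one channel,
    mapping event times back to record time."""
    fs = epoched.recording.fs
    x, eps = epoched.concatenate(stage, channel)
    if x.size < 10 * fs:
        return []
    events = detect_so(x, fs, thresholds)
    n = int(round(EPOCH_SECONDS * fs))

    def tmap(t: float) -> float:
        s = int(round(t * fs))
        e = eps[min(s // n, len(eps) - 1)]
        return e * EPOCH_SECONDS + (s % n) / fs

    out = []
    for ev in events:
        span = ev.end_zc_s - ev.down_zc_s
        if abs((tmap(ev.end_zc_s) - tmap(ev.down_zc_s)) - span) > 1.5 / fs:
            continue  # straddles non-adjacent epochs
        out.append(SOEvent(
            channel=channel,
            down_zc_s=tmap(ev.down_zc_s), up_zc_s=tmap(ev.up_zc_s),
            end_zc_s=tmap(ev.end_zc_s),
            neg_peak_time_s=tmap(ev.neg_peak_time_s),
            pos_peak_time_s=tmap(ev.pos_peak_time_s),
            neg_peak_uv=ev.neg_peak_uv, pos_peak_uv=ev.pos_peak_uv,
            p2p_uv=ev.p2p_uv, duration_s=ev.duration_s,
            slope_uv_per_s=ev.slope_uv_per_s))
    return out


def so_metrics(events: list[SOEvent], retained_minutes: float) -> dict:
    """Density and mean morphology of a channel's SOs."""
    n = len(events)
    out = {"n_events": n,
           "density": n / retained_minutes if retained_minutes > 0 else np.nan}
    for name, attr in (("neg_peak", "neg_peak_uv"), ("p2p", "p2p_uv"),
                       ("duration", "duration_s"), ("slope", "slope_uv_per_s")):
        vals = np.array([getattr(e, attr) for e in events], dtype=float)
        out[name] = float(np.nanmean(vals)) if n else np.nan
    return out


def events_frame(events: list[SOEvent]) -> pd.DataFrame:
    cols = ["channel", "down_zc_s", "up_zc_s", "end_zc_s", "neg_peak_time_s",
            "pos_peak_time_s", "neg_peak_uv", "pos_peak_uv", "p2p_uv",
            "duration_s", "slope_uv_per_s"]
    return pd.DataFrame([e.__dict__ for e in events], columns=cols)
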