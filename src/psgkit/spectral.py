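"""Welch spectral power per stage and channel, summarized by band.

Per 30-s epoch the PSD is estimated with 4-s segments (0.25 Hz
resolution), a Tukey (50 %) taper and 50 % segment overlap; segment
PSDs are averaged within the epoch and then across retained epochs.
Densities are one-sided µV²/Hz with the taper power compensated
(scipy's ``density`` scaling), so rectangular band integration of a
unit-variance sinusoid recovers 1 µV² up to taper leakage.

Band powers use half-open intervals [lo, hi): a bin at exactly 12 Hz
belongs to sigma, not alpha.  Absolute powers are natural-log
transformed for analysis; non-positive values propagate as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .hypnogram import EPOCH_SECONDS

#: classical frequency bands (Hz), half-open [lo, hi)
DEFAULT_BANDS = {
    "slow": (0.5, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "sigma": (12.0, 15.0),
    "beta": (15.0, 30.0),
    "total": (0.5, 35.0),
}


@dataclass
class BandScheme:
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    total_band: str = "total"

    def validate(self) -> None:
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name}: lo must be < hi")
            if lo < 0.5 - 1e-9 or hi > 35.0 + 1e-9:
                raise ValueError(f"band {name}: outside 0.5-35 Hz")


def welch_psd(epochs: np.ndarray, fs: float,
              segment_s: float = 4.0) -> tuple[np.ndarray, np.ndarray]:
    """Average Welch PSD over a stack of 30-s epochs.

    Parameters
    ----------
    epochs : ndarray, shape (n_epochs, n_samples) or (n_samples,)
        Retained 30-s epochs in µV.
    fs : float
        Sampling frequency.

    Returns
    -------
    freqs, psd : 0.25 Hz-resolution frequency grid and one-sided power
        spectral density in µV²/Hz.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    nper = int(round(segment_s * fs))
    if epochs.shape[-1] < nper:
        raise ValueError(
            f"epoch shorter than one {segment_s:.0f}-s Welch segment")
    f, p = sps.welch(epochs, fs=fs, window=("tukey", 0.5), nperseg=nper,
                     noverlap=nper // 2, detrend=False, axis=-1,
                     scaling="density")
    return f, p.mean(axis=0)


def band_powers(freqs: np.ndarray, psd: np.ndarray,
                scheme: BandScheme | None = None) -> pd.DataFrame:
    """Rectangular band integration of a PSD.

    Returns a DataFrame indexed by band with columns ``absolute``
    (µV²), ``log_absolute`` (natural log, NaN when power is not
    positive) and ``relative`` (fraction of the total band, NaN when
    total power is zero).
    """
    scheme = scheme or BandScheme()
    scheme.validate()
    df = float(freqs[1] - freqs[0])
    rows = {}
    for name, (lo, hi) in scheme.bands.items():
        m = (freqs >= lo - 1e-9) & (freqs < hi - 1e-9)
        rows[name] = float(psd[m].sum() * df)
    total = rows.get(scheme.total_band, np.nan)
    out = pd.DataFrame({
        "absolute": pd.Series(rows),
        "log_absolute": pd.Series(
            {k: np.log(v) if v > 0 else np.nan for k, v in rows.items()}),
        "relative": pd.Series(
            {k: v / total if total > 0 else np.nan for k, v in rows.items()}),
    })
    out.index.name = "band"
    return out


def stage_band_summary(epoched, stages=("N2", "N3", "R"),
                       scheme: BandScheme | None = None) -> pd.DataFrame:
    """Band-power summary for every (stage, channel) with retained epochs.

    Long format: record-ready rows with stage, channel, band, absolute,
    log_absolute, relative.
    """
    rec = epoched.recording
    n = int(round(EPOCH_SECONDS * rec.fs))
    rows = []
    for stage in stages:
        for ch in rec.channels:
            eps = epoched.kept_epochs(stage, ch)
            if len(eps) == 0:
                continue
            stack = np.stack([epoched.epoch_data(e, ch)[:n] for e in eps])
            f, p = welch_psd(stack, rec.fs)
            bp = band_powers(f, p, scheme)
            for band, r in bp.iterrows():
                rows.append({"stage": stage, "channel": ch, "band": band,
                             "n_epochs": len(eps), **r.to_dict()})
    return pd.DataFrame(rows)
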