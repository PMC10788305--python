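"""EEG preprocessing: referencing, resampling, filtering, line-noise
removal, stage-wise epoching, artifact rejection, polarity resolution
and record-level exclusions.

The cleaning cascade follows standard practice for clinical PSG:

1. re-reference F3/C3/O1 to M2 and F4/C4/O2 to M1 (contralateral mastoid);
2. down-sample signals above 200 Hz to 200 Hz;
3. remove mains interference by spectrum interpolation (the amplitude
   spectrum in a narrow band around the mains frequency and its first
   harmonic is replaced by log-linear interpolation of the flanking
   amplitudes, preserving phase);
4. zero-phase band-pass 0.5-35 Hz (4th-order Butterworth, forward-backward);
5. per stage, flag 30-s epochs whose maximum amplitude exceeds 200 µV,
   that are flat or clipped for more than 10 % of their samples, or that
   are Hjorth-parameter outliers (3 SD against the individual's
   all-channel distribution, 4 SD against the same channel, 4 SD against
   all channels pooled; the Hjorth passes are run twice with statistics
   recomputed on survivors); channels with more than half of their
   epochs flagged are dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats as spstats

from .hypnogram import Hypnogram, EPOCH_SECONDS
from .recording import Recording, EEG_CHANNELS, CONTRALATERAL_MASTOID

TARGET_FS = 200.0
BANDPASS = (0.5, 35.0)
SO_BAND = (0.5, 4.0)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def bandpass_filter(x: np.ndarray, fs: float, lo: float, hi: float,
                    order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward)."""
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def remove_line_noise(x: np.ndarray, fs: float, mains: float = 60.0,
                      half_width: float = 1.0, flank: float = 2.0,
                      n_harmonics: int = 2) -> np.ndarray:
    """Spectrum-interpolation mains removal.

    For each harmonic k*mains below Nyquist, the FFT amplitude in
    [k*mains - half_width, k*mains + half_width] is replaced by
    log-linear interpolation between the mean amplitudes of the two
    flanking bands of width ``flank``; phase is preserved.
    """
    orig_ndim = np.ndim(x)
    x = np.atleast_2d(x)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.abs(spec)
    phase = np.angle(spec)
    for k in range(1, n_harmonics + 1):
        f0 = k * mains
        if f0 >= fs / 2.0 - half_width:
            break
        band = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
        left = (freqs >= f0 - half_width - flank) & (freqs < f0 - half_width)
        right = (freqs > f0 + half_width) & (freqs <= f0 + half_width + flank)
        if not band.any() or not left.any() or not right.any():
            continue
        la = np.log(np.maximum(amp[..., left].mean(axis=-1), 1e-30))
        ra = np.log(np.maximum(amp[..., right].mean(axis=-1), 1e-30))
        fl = freqs[left].mean()
        fr = freqs[right].mean()
        w = (freqs[band] - fl) / (fr - fl)
        amp[..., band] = np.exp(la[..., None] * (1 - w) + ra[..., None] * w)
    out = np.fft.irfft(amp * np.exp(1j * phase), n, axis=-1)
    return out[0] if orig_ndim == 1 else out


@dataclass
class PreprocessConfig:
    mains: float = 60.0
    target_fs: float = TARGET_FS
    bandpass: tuple = BANDPASS
    line_half_width: float = 1.0
    reference: bool = True
    remove_mains: bool = True


def preprocess(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Reference, resample, de-noise and band-pass a recording.

    Returns a new Recording containing the six EEG channels only,
    contralaterally mastoid-referenced (when mastoids are present and
    ``cfg.reference`` is set), at <= 200 Hz, mains-cleaned and 0.5-35 Hz
    band-passed.
    """
    cfg = cfg or PreprocessConfig()
    if rec.fs < 100:
        raise ValueError("sampling rate below 100 Hz is not supported")

    chans = [c for c in EEG_CHANNELS if c in rec.channels]
    if not chans:
        raise ValueError(f"no EEG channels found among {rec.channels}")
    data = np.stack([rec.get(c) for c in chans])
    reference = {}
    if cfg.reference:
        missing = [CONTRALATERAL_MASTOID[c] for c in chans
                   if CONTRALATERAL_MASTOID[c] not in rec.channels]
        if missing:
            raise ValueError(
                f"mastoid channel(s) {sorted(set(missing))} absent; "
                "re-referencing requires M1 and M2")
        for i, c in enumerate(chans):
            data[i] = data[i] - rec.get(CONTRALATERAL_MASTOID[c])
            reference[c] = CONTRALATERAL_MASTOID[c]
    else:
        reference = {c: rec.reference.get(c, "raw") for c in chans}

    fs = rec.fs
    if fs > cfg.target_fs:
        n_out = int(round(data.shape[1] * cfg.target_fs / fs))
        data = sps.resample_poly(data, int(cfg.target_fs), int(fs), axis=-1)[:, :n_out]
        fs = cfg.target_fs

    if cfg.remove_mains:
        data = remove_line_noise(data, fs, cfg.mains, cfg.line_half_width)
    data = bandpass_filter(data, fs, *cfg.bandpass)
    return Recording(chans, data, fs, reference, rec.start_time)


# ---------------------------------------------------------------------------
# Hjorth parameters
# ---------------------------------------------------------------------------


def hjorth(x: np.ndarray) -> tuple[float, float, float, bool]:
    """Hjorth activity, mobility and complexity of one epoch.

    activity  = var(x)                        [µV²]
    mobility  = sqrt(var(dx) / var(x))        [unitless]
    complexity = mobility(dx) / mobility(x)   [unitless]

    Returns (activity, mobility, complexity, degenerate); a
    zero-variance input yields (0, 0, 0, True).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite samples")
    v0 = x.var()
    if v0 <= 0:
        return 0.0, 0.0, 0.0, True
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1 = d1.var()
    v2 = d2.var()
    mob = np.sqrt(v1 / v0)
    comp = np.sqrt(v2 / v1) / mob if v1 > 0 else 0.0
    return float(v0), float(mob), float(comp), False


# ---------------------------------------------------------------------------
# epoching + artifact rejection
# ---------------------------------------------------------------------------


@dataclass
class RejectionThresholds:
    max_amp_uv: float = 200.0
    flat_eps_uv: float = 0.05       # |first difference| below this = flat
    flat_clip_prop: float = 0.10    # flagged if flat/clipped > this share
    hjorth_sd_all: float = 3.0      # vs individual's all-channel pool
    hjorth_sd_chan: float = 4.0     # vs same-channel epochs
    hjorth_sd_pool: float = 4.0     # vs all-channel all-epoch pool
    hjorth_passes: int = 2
    channel_drop_prop: float = 0.50


@dataclass
class EpochedRecording:
    """30-s stage-labelled epochs with per-(epoch, channel) QC state."""

    recording: Recording
    hypnogram: Hypnogram
    qc: pd.DataFrame            # epoch, channel, stage, kept, reasons
    hjorth_params: pd.DataFrame  # epoch, channel, stage, activity, mobility, complexity
    dropped_channels: dict = field(default_factory=dict)  # stage -> list

    def epoch_data(self, epoch: int, channel: str) -> np.ndarray:
        n = int(round(EPOCH_SECONDS * self.recording.fs))
        ci = self.recording.channels.index(channel)
        return self.recording.data[ci, epoch * n:(epoch + 1) * n]

    def kept_epochs(self, stage: str, channel: str) -> np.ndarray:
        q = self.qc
        m = (q["stage"] == stage) & (q["channel"] == channel) & q["kept"]
        return np.sort(q.loc[m, "epoch"].to_numpy())

    def kept_minutes(self, stage: str, channel: str) -> float:
        return len(self.kept_epochs(stage, channel)) * EPOCH_SECONDS / 60.0

    def concatenate(self, stage: str, channel: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated samples of retained epochs and their epoch indices."""
        eps = self.kept_epochs(stage, channel)
        segs = [self.epoch_data(e, channel) for e in eps]
        if not segs:
            return np.zeros(0), eps
        return np.concatenate(segs), eps


def epoch_record(rec: Recording, hyp: Hypnogram) -> EpochedRecording:
    """Slice a recording into 30-s epochs on the staging grid."""
    n = int(round(EPOCH_SECONDS * rec.fs))
    n_epochs = min(hyp.n_epochs, rec.n_samples // n)
    rows = []
    for e in range(n_epochs):
        for ch in rec.channels:
            rows.append({"epoch": e, "channel": ch, "stage": hyp.stages[e],
                         "kept": True, "reasons": ""})
    qc = pd.DataFrame(rows)
    hj = pd.DataFrame(columns=["epoch", "channel", "stage",
                               "activity", "mobility", "complexity"])
    return EpochedRecording(rec, Hypnogram(hyp.stages[:n_epochs]), qc, hj)


def _flag(qc: pd.DataFrame, idx, reason: str) -> None:
    idx = np.atleast_1d(idx)
    qc.loc[idx, "kept"] = False
    for i in idx:
        cur = qc.at[i, "reasons"]
        qc.at[i, "reasons"] = reason if cur == "" else cur + ";" + reason


def reject_artifacts(epoched: EpochedRecording,
                     thresholds: RejectionThresholds | None = None,
                     stages: tuple = ("N2", "N3", "R")) -> EpochedRecording:
    """Flag artifactual (epoch, channel) pairs, stage by stage.

    Rules, applied per stage and channel:
      (a) any |sample| > 200 µV;
      (b) flat (|dx| < eps) or clipped (samples at the epoch's own
          extrema) for more than 10 % of the epoch;
      (c) any Hjorth parameter > 3 SD from the individual's all-channel
          mean for that stage;
      (d) > 4 SD from the same channel's epoch mean;
      (e) > 4 SD from the all-channel all-epoch mean.
    The Hjorth rules (c-e) run twice, recomputing statistics on
    survivors.  Channels with more than 50 % of a stage's epochs flagged
    are dropped for that stage.
    """
    th = thresholds or RejectionThresholds()
    rec, qc = epoched.recording, epoched.qc
    n = int(round(EPOCH_SECONDS * rec.fs))
    hj_rows = []

    for stage in stages:
        sel = qc.index[qc["stage"] == stage]
        if not len(sel):
            continue
        stage_epochs = qc.loc[sel, "epoch"].unique()
        if len(stage_epochs) < 2:
            _flag_warn = True  # too few epochs: skip rejection for this stage
            continue

        # --- amplitude / flat / clip rules + Hjorth values
        for i in sel:
            e, ch = qc.at[i, "epoch"], qc.at[i, "channel"]
            x = epoched.epoch_data(e, ch)
            if np.max(np.abs(x)) > th.max_amp_uv:
                _flag(qc, i, "max_amp")
            dx = np.abs(np.diff(x))
            flat = (dx < th.flat_eps_uv).mean()
            clip = np.mean((x == x.max()) | (x == x.min())) if x.size else 0.0
            if flat > th.flat_clip_prop or clip > th.flat_clip_prop:
                _flag(qc, i, "flat_clip")
            a, m, c, degen = hjorth(x)
            hj_rows.append({"epoch": e, "channel": ch, "stage": stage,
                            "activity": a, "mobility": m, "complexity": c})
            if degen and qc.at[i, "kept"]:
                _flag(qc, i, "flat_clip")

        hj = pd.DataFrame([r for r in hj_rows if r["stage"] == stage])
        hj = hj.merge(qc[["epoch", "channel", "kept"]], on=["epoch", "channel"])

        # --- Hjorth outlier passes
        for _ in range(th.hjorth_passes):
            live = hj[hj["kept"]]
            if len(live) < 3:
                break
            flag_pairs = set()
            for param in ("activity", "mobility", "complexity"):
                pool = live[param].to_numpy()
                mu_all, sd_all = pool.mean(), pool.std()
                for ch, grp in live.groupby("channel"):
                    v = grp[param].to_numpy()
                    mu_ch, sd_ch = v.mean(), v.std()
                    for _, row in grp.iterrows():
                        x = row[param]
                        out = False
                        if sd_all > 0 and abs(x - mu_all) > th.hjorth_sd_all * sd_all:
                            out = True
                        if sd_ch > 0 and abs(x - mu_ch) > th.hjorth_sd_chan * sd_ch:
                            out = True
                        if sd_all > 0 and abs(x - mu_all) > th.hjorth_sd_pool * sd_all:
                            out = True
                        if out:
                            flag_pairs.add((row["epoch"], row["channel"]))
            if not flag_pairs:
                break
            for e, ch in flag_pairs:
                idx = qc.index[(qc["epoch"] == e) & (qc["channel"] == ch)]
                _flag(qc, idx, "hjorth")
                hj.loc[(hj["epoch"] == e) & (hj["channel"] == ch), "kept"] = False

        # --- channel drop rule
        for ch in rec.channels:
            m = (qc["stage"] == stage) & (qc["channel"] == ch)
            if m.any() and (~qc.loc[m, "kept"]).mean() > th.channel_drop_prop:
                _flag(qc, qc.index[m & qc["kept"]], "channel_drop")
                epoched.dropped_channels.setdefault(stage, []).append(ch)

    epoched.hjorth_params = pd.DataFrame(
        hj_rows, columns=["epoch", "channel", "stage",
                          "activity", "mobility", "complexity"])
    return epoched


# ---------------------------------------------------------------------------
# polarity
# ---------------------------------------------------------------------------


def t_diff(epoched: EpochedRecording, channel: str, stage: str = "N2") -> float:
    """Polarity statistic: standardized per-epoch skewness of the
    0.5-4 Hz signal (mean over epochs divided by their SD).

    Physiologic slow oscillations have deep negative half-waves, giving
    negatively skewed delta-band epochs, hence T_DIFF < 0 for a
    correctly oriented channel; the decision rule reads: > 1 flip,
    < -1 keep, in between ambiguous.  Standardizing by the SD (an
    effect size, not a standard error) keeps the fixed +/-1 cutoffs
    meaningful regardless of record length: symmetric noise stays in
    the ambiguous band rather than drifting out as epochs accumulate.
    The statistic is odd under global negation.
    """
    eps = epoched.kept_epochs(stage, channel)
    skews = []
    fs = epoched.recording.fs
    for e in eps:
        x = epoched.epoch_data(e, channel)
        xf = bandpass_filter(x, fs, *SO_BAND)
        skews.append(spstats.skew(xf))
    skews = np.asarray(skews)
    if len(skews) < 2 or skews.std(ddof=1) == 0:
        return 0.0
    return float(skews.mean() / skews.std(ddof=1))


def resolve_polarity(epoched: EpochedRecording,
                     channels: tuple = ("C3", "C4"),
                     min_epochs: int = 10) -> dict:
    """Classify channel polarity from N2 delta-band skewness.

    Returns {"decision": "normal" | "flipped" | "ambiguous",
    "t_diff": {channel: value}}.  T_DIFF > 1 on any tested channel means
    the recording is flipped; T_DIFF < -1 on all means normal; values in
    the closed interval [-1, 1] are ambiguous.
    """
    tvals = {}
    for ch in channels:
        if ch not in epoched.recording.channels:
            continue
        if len(epoched.kept_epochs("N2", ch)) < min_epochs:
            tvals[ch] = np.nan
            continue
        tvals[ch] = t_diff(epoched, ch)
    if not tvals or any(np.isnan(v) for v in tvals.values()):
        return {"decision": "ambiguous", "t_diff": tvals}
    if any(v > 1.0 for v in tvals.values()):
        decision = "flipped"
    elif all(v < -1.0 for v in tvals.values()):
        decision = "normal"
    else:
        decision = "ambiguous"
    return {"decision": decision, "t_diff": tvals}


# ---------------------------------------------------------------------------
# record-level exclusions
# ---------------------------------------------------------------------------


@dataclass
class ExclusionReport:
    record_kept: bool
    reasons: list
    polarity: dict = field(default_factory=dict)


def spk(epoched: EpochedRecording, channel: str, stage: str,
        mains: float = 60.0) -> float:
    """Residual line-noise index: mean Welch power in mains +/- 0.5 Hz
    over median power in the 45-55 Hz flank (requires fs > 2*mains not
    enforced; with 200 Hz sampling the 60 Hz band is observable)."""
    x, _ = epoched.concatenate(stage, channel)
    if x.size < int(4 * epoched.recording.fs):
        return np.nan
    f, p = sps.welch(x, fs=epoched.recording.fs, nperseg=int(4 * epoched.recording.fs))
    band = (f >= mains - 0.5) & (f <= mains + 0.5)
    flank = (f >= 45) & (f <= 55)
    if not band.any() or not flank.any():
        return np.nan
    med = np.median(p[flank])
    return float(p[band].mean() / med) if med > 0 else np.nan


def apply_record_exclusions(tst_minutes: float,
                            stage_epoch_counts: dict,
                            polarity: dict | None = None,
                            spk_z: dict | None = None,
                            power_1hz_z: dict | None = None,
                            power_25hz_z: dict | None = None,
                            min_tst: float = 180.0,
                            min_stage_epochs: int = 10) -> ExclusionReport:
    """Assemble the record-level exclusion report.

    Cohort-referenced rules (SPK > 5 SD; 1 Hz power outside +/- 4 SD;
    25 Hz power above +4 SD) apply only when the corresponding z-scores
    are supplied; in single-record mode they are skipped.
    """
    reasons = []
    if tst_minutes < min_tst:
        reasons.append("tst_lt_180")
    if any(v < min_stage_epochs for v in stage_epoch_counts.values()):
        reasons.append("stage_epochs_lt_10")
    if spk_z and any(np.isfinite(v) and v > 5.0 for v in spk_z.values()):
        reasons.append("spk_gt_5sd")
    if power_1hz_z and any(np.isfinite(v) and abs(v) > 4.0
                           for v in power_1hz_z.values()):
        reasons.append("power_outlier_1hz")
    if power_25hz_z and any(np.isfinite(v) and v > 4.0
                            for v in power_25hz_z.values()):
        reasons.append("power_outlier_25hz")
    if polarity and polarity.get("decision") == "ambiguous":
        reasons.append("polarity_ambiguous")
    return ExclusionReport(record_kept=not reasons, reasons=reasons,
                           polarity=polarity or {})
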