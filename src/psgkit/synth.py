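"""Ground-truthed synthetic polysomnography.

Generates stage-structured multichannel EEG with a 1/f^alpha aperiodic
background, implanted sleep spindles (Hann-windowed sinusoids with a
linear intra-event frequency ramp), implanted slow oscillations
(biphasic raised-cosine waves), von-Mises-concentrated SO-phase
coupling of spindle peaks, injectable artifacts, and age-structured
cohorts.  Every implanted event and artifact is logged, so detector
recall, precision, morphology recovery and coupling calibration can be
scored against exact ground truth.

All randomness flows from a single integer seed through a hierarchical
``numpy.random.SeedSequence`` substream scheme (record -> channel ->
event class), so regenerating one channel or one subject is stable
under changes elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, EPOCH_SECONDS
from .recording import Recording, EEG_CHANNELS

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class HypnogramParams:
    """Generative parameters for a night's stage sequence.

    ``stage_dwell`` gives relative within-cycle NREM composition weights
    (minutes-scale); ``rem_fraction`` the share of each cycle spent in R.
    """

    n_cycles: int = 4
    cycle_minutes: float = 90.0
    stage_dwell: dict = field(default_factory=lambda: {"N1": 4.0, "N2": 40.0, "N3": 28.0})
    rem_fraction: float = 0.2
    wake_onset_minutes: float = 10.0
    waso_rate: float = 1.0          # brief awakenings per hour after onset
    waso_minutes: float = 1.0       # mean awakening bout length
    jitter: float = 0.15            # lognormal CV applied to bout lengths

    def validate(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.cycle_minutes <= 0 or self.waso_minutes <= 0:
            raise ValueError("durations must be positive")
        if not 0 <= self.rem_fraction <= 1:
            raise ValueError("rem_fraction must be in [0, 1]")
        if any(v <= 0 for v in self.stage_dwell.values()):
            raise ValueError("stage dwell times must be positive")
        if self.wake_onset_minutes < 0 or self.waso_rate < 0:
            raise ValueError("wake parameters must be non-negative")


@dataclass
class SubjectProfile:
    subject_id: str
    age: float
    sex: str = "F"
    race: str = "white"
    group: str = "non-NDD"
    ahi: float = 1.0
    medication: bool = False
    #: developmental delay (<0) or advance (>0) in years applied to every
    #: feature-generating age curve
    trajectory_offset: float = 0.0


#: default implant channels per event class
CLASS_CHANNELS = {
    "slow_spindle": ("F3", "F4"),
    "fast_spindle": ("C3", "C4"),
    "so": ("F3", "F4", "C3", "C4"),
}


@dataclass
class EventSpec:
    """Parameters of one implanted event class.

    For spindles ``amplitude`` is the peak of the Hann envelope (µV) and
    ``chirp`` the total linear change in instantaneous frequency from
    event start to end (Hz; negative = deceleration).  The half-based
    chirp estimator recovers half of this ramp.  For SOs ``amplitude``
    is the negative-peak magnitude and ``p2p`` the peak-to-peak
    amplitude; ``duration`` spans both half-waves.
    """

    event_class: str                  # slow_spindle | fast_spindle | so
    density: float = 2.0              # events per minute of eligible stage time
    amplitude: float = 30.0           # µV (pediatric spindles are high-amplitude)
    duration: float = 1.0             # s
    frequency: float = 13.5           # Hz (carrier; ignored for SO)
    chirp: float = 0.0                # Hz, end minus start instantaneous freq
    p2p: float | None = None          # µV, SO only (default 1.6 x amplitude)
    coupling_phase: float = 0.0       # degrees, SO phase of spindle peak
    coupling_kappa: float = 0.0       # von Mises concentration; 0 = uncoupled
    channels: tuple | None = None     # None -> class default topography
    stages: tuple = ("N2",)
    amp_jitter_cv: float = 0.0        # lognormal CV on per-event amplitude
    freq_jitter_sd: float = 0.0       # Hz, normal jitter on carrier

    def validate(self) -> None:
        if self.event_class not in CLASS_CHANNELS:
            raise ValueError(f"unknown event class {self.event_class!r}")
        if self.density < 0:
            raise ValueError("density must be >= 0")
        if self.duration <= 0 or self.amplitude <= 0:
            raise ValueError("duration and amplitude must be positive")
        if self.coupling_kappa < 0:
            raise ValueError("coupling_kappa must be >= 0")

    @property
    def resolved_channels(self) -> tuple:
        return self.channels if self.channels is not None else CLASS_CHANNELS[self.event_class]


@dataclass
class NoiseParams:
    """Aperiodic 1/f^alpha background, per stage (units µV RMS)."""

    rms: dict = field(default_factory=lambda: {
        "W": 15.0, "N1": 18.0, "N2": 20.0, "N3": 40.0, "R": 15.0})
    alpha: dict = field(default_factory=lambda: {
        "W": 1.2, "N1": 1.4, "N2": 1.5, "N3": 2.0, "R": 1.2})
    #: amplitude of posterior waking alpha (10 Hz) on O1/O2, µV
    wake_alpha_uv: float = 5.0
    #: amplitude of diffuse R-stage theta (5 Hz), µV
    rem_theta_uv: float = 3.0
    mastoid_rms: float = 2.0


@dataclass
class GroundTruth:
    events: pd.DataFrame            # class, channel, start_s, stop_s, peak_s, phase_at_peak_deg
    artifact_log: pd.DataFrame      # channel, epoch_index, kind
    true_features: dict


# ---------------------------------------------------------------------------
# hypnogram simulation
# ---------------------------------------------------------------------------


def _bout_epochs(minutes: float, cv: float, rng: np.random.Generator) -> int:
    """Lognormal-jittered bout length rounded to whole 30-s epochs (>=1)."""
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        minutes = minutes * rng.lognormal(-sigma**2 / 2, sigma)
    return max(1, int(round(minutes * 60.0 / EPOCH_SECONDS)))


def simulate_hypnogram(params: HypnogramParams, seed: int) -> Hypnogram:
    """Generate a night of 30-s stage labels with the requested cycle count.

    Each cycle is an ascending-descending NREM block (N1, N2, N3, N2)
    followed by an R period; brief awakenings are inserted after sleep
    onset at ``waso_rate`` events per hour.  Deterministic given
    (params, seed).
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    labels: list[str] = []

    labels += ["W"] * int(round(params.wake_onset_minutes * 60 / EPOCH_SECONDS))

    nrem_minutes = params.cycle_minutes * (1.0 - params.rem_fraction)
    rem_minutes = params.cycle_minutes * params.rem_fraction
    dwell_total = sum(params.stage_dwell.values())
    for c in range(params.n_cycles):
        # deep sleep front-loaded: N3 share decays over the night
        n3_scale = max(0.25, 1.0 - 0.25 * c)
        weights = dict(params.stage_dwell)
        weights["N3"] = weights.get("N3", 0.0) * n3_scale
        wtot = sum(weights.values())
        for stage, seq_share in (("N1", 1.0), ("N2", 0.55), ("N3", 1.0), ("N2", 0.45)):
            w = weights.get(stage, 0.0) / wtot
            minutes = nrem_minutes * w * seq_share if stage == "N2" else nrem_minutes * w
            if minutes <= 0:
                continue
            labels += [stage] * _bout_epochs(minutes, params.jitter, rng)
        # R period: first one may be short, later ones grow
        rem_scale = 0.6 if c == 0 else 1.0 + 0.15 * c
        labels += ["R"] * _bout_epochs(rem_minutes * rem_scale, params.jitter, rng)

    stages = np.asarray(labels, dtype=object)

    # brief awakenings after sleep onset (never inside the first epoch of
    # a stage bout, so cycle structure is preserved)
    onset = int(round(params.wake_onset_minutes * 60 / EPOCH_SECONDS))
    hours = (len(stages) - onset) * EPOCH_SECONDS / 3600.0
    n_waso = rng.poisson(params.waso_rate * hours) if params.waso_rate > 0 else 0
    for _ in range(n_waso):
        pos = int(rng.integers(onset + 1, len(stages) - 1))
        bout = _bout_epochs(params.waso_minutes, params.jitter, rng)
        stages = np.concatenate([stages[:pos], ["W"] * bout, stages[pos:]])
    return Hypnogram(stages)


# ---------------------------------------------------------------------------
# waveforms
# ---------------------------------------------------------------------------


def spindle_waveform(fs: float, duration: float, frequency: float,
                     chirp: float, amplitude: float, phase0: float = 0.0) -> np.ndarray:
    """Hann-windowed sinusoid with a linear instantaneous-frequency ramp.

    The instantaneous frequency runs from ``frequency - chirp/2`` to
    ``frequency + chirp/2`` (symmetric about the carrier), i.e. the
    total intra-event frequency change equals ``chirp``.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # phase = 2*pi * integral of f(t) = f0 + chirp*(t/D - 1/2)
    phase = 2 * np.pi * (frequency * t + chirp * (t**2 / (2 * duration) - t / 2.0))
    env = amplitude * np.sin(np.pi * t / duration) ** 2
    return env * np.cos(phase + phase0)


def so_waveform(fs: float, neg_duration: float, pos_duration: float,
                neg_peak: float, p2p: float) -> np.ndarray:
    """Biphasic raised-cosine slow oscillation.

    A negative half-wave of ``neg_duration`` with peak ``-neg_peak``
    followed by a positive half-wave of ``pos_duration`` with peak
    ``p2p - neg_peak``.
    """
    n_neg = int(round(neg_duration * fs))
    n_pos = int(round(pos_duration * fs))
    t_neg = np.arange(n_neg) / fs
    t_pos = np.arange(n_pos) / fs
    neg = -neg_peak * np.sin(np.pi * t_neg / neg_duration) ** 2
    pos = (p2p - neg_peak) * np.sin(np.pi * t_pos / pos_duration) ** 2
    return np.concatenate([neg, pos])


def so_phase_to_time(phase_deg: float, start: float, neg_duration: float,
                     pos_duration: float) -> float:
    """Map an SO phase (0 deg = positive peak, 180 deg = negative peak,
    increasing with time) to a time inside the event.

    The event spans phases 90 deg (down zero-crossing) through 450 deg
    (end zero-crossing), with anchors at the negative peak (180), the
    up zero-crossing (270) and the positive peak (360).
    """
    p = phase_deg % 360.0
    if p < 90.0:
        p += 360.0
    anchors_phase = np.array([90.0, 180.0, 270.0, 360.0, 450.0])
    anchors_time = start + np.array([
        0.0, neg_duration / 2.0, neg_duration,
        neg_duration + pos_duration / 2.0, neg_duration + pos_duration])
    return float(np.interp(p, anchors_phase, anchors_time))


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def powerlaw_noise(n: int, fs: float, alpha: float, rms: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Gaussian 1/f^alpha noise via spectral shaping, scaled to target RMS."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    # flatten below 0.5 Hz so slow drift does not dominate the variance
    shape[nz] = np.maximum(f[nz], 0.5) ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


# ---------------------------------------------------------------------------
# record synthesis
# ---------------------------------------------------------------------------


def _stage_segments(hyp: Hypnogram, stages: tuple) -> list[tuple[float, float]]:
    """Contiguous runs of the given stages as (start_s, stop_s)."""
    mask = np.isin(hyp.stages, stages)
    segs = []
    i = 0
    while i < len(mask):
        if mask[i]:
            j = i
            while j < len(mask) and mask[j]:
                j += 1
            segs.append((i * hyp.epoch_seconds, j * hyp.epoch_seconds))
            i = j
        else:
            i += 1
    return segs


def _place_events(spec: EventSpec, segments: list, existing: list,
                  rng: np.random.Generator, min_gap: float = 1.0,
                  max_tries: int = 5000) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping (start, stop) intervals in segments."""
    minutes = sum(b - a for a, b in segments) / 60.0
    n_events = int(round(spec.density * minutes))
    roomy = [(a, b) for a, b in segments if b - a > spec.duration + 2 * min_gap]
    if n_events > 0 and not roomy:
        raise ValueError(
            f"density {spec.density}/min infeasible: no {'/'.join(spec.stages)} "
            f"segment can hold a {spec.duration:.2f}-s event")
    lengths = np.array([b - a - spec.duration for a, b in roomy], dtype=float)
    weights = lengths / lengths.sum() if len(lengths) else None
    placed = []
    occupied = list(existing)
    for _ in range(n_events):
        for attempt in range(max_tries):
            k = rng.choice(len(roomy), p=weights)
            a, b = roomy[k]
            start = rng.uniform(a, b - spec.duration)
            stop = start + spec.duration
            if all(stop + min_gap <= s or start - min_gap >= e for s, e in occupied):
                placed.append((start, stop))
                occupied.append((start, stop))
                break
        else:
            raise ValueError(
                f"density {spec.density}/min infeasible for available "
                f"{'/'.join(spec.stages)} time ({minutes:.1f} min)")
    return placed


def _so_split(duration: float) -> tuple[float, float]:
    """Split an SO duration into negative and positive half-wave durations
    respecting the detector's temporal criteria (0.3-1.5 s and <= 1 s)."""
    d_n = float(np.clip(duration * 0.55, 0.3, 1.5))
    d_p = float(np.clip(duration - d_n, 0.2, 1.0))
    return d_n, d_p


def synthesize_record(profile: SubjectProfile, hypnogram: Hypnogram,
                      specs: list[EventSpec], noise: NoiseParams | None = None,
                      fs: float = 200.0, seed: int = 0,
                      include_mastoids: bool = True,
                      channels: list | None = None) -> tuple[Recording, GroundTruth]:
    """Build a six-channel µV record from a hypnogram and event specs.

    The signal is the sum of stage-dependent 1/f^alpha background,
    mild stage oscillations (posterior waking alpha, diffuse R theta)
    and the implanted events.  When ``coupling_kappa > 0`` for a
    spindle class, every spindle peak of that class is placed at an SO
    phase drawn from von Mises(coupling_phase, kappa) inside a randomly
    chosen same-channel SO.
    """
    if fs not in (128.0, 200.0, 256.0, 512.0, 128, 200, 256, 512):
        raise ValueError("fs must be one of 128, 200, 256, 512 Hz")
    noise = noise or NoiseParams()
    for s in specs:
        s.validate()

    root = np.random.SeedSequence(seed)
    n_samples = int(round(hypnogram.duration_s * fs))
    if channels is None:
        channels = list(EEG_CHANNELS) + (["M1", "M2"] if include_mastoids else [])
    else:
        channels = list(channels)
    data = np.zeros((len(channels), n_samples))

    ch_seeds = root.spawn(len(channels) + 1)
    event_rows = []

    for ci, ch in enumerate(channels):
        rng = np.random.default_rng(ch_seeds[ci])
        if ch in ("M1", "M2"):
            if noise.mastoid_rms > 0:
                data[ci] = powerlaw_noise(n_samples, fs, 1.0, noise.mastoid_rms, rng)
            continue
        # stage-wise aperiodic background + stage oscillations
        for label, a, b in _runs(hypnogram.stages):
            i0, i1 = int(a * hypnogram.epoch_seconds * fs), int(b * hypnogram.epoch_seconds * fs)
            seg = powerlaw_noise(i1 - i0, fs, noise.alpha[label], noise.rms[label], rng)
            t = np.arange(i0, i1) / fs
            if label == "W" and ch in ("O1", "O2") and noise.wake_alpha_uv > 0:
                seg = seg + noise.wake_alpha_uv * np.sin(2 * np.pi * 10.0 * t)
            if label == "R" and noise.rem_theta_uv > 0:
                seg = seg + noise.rem_theta_uv * np.sin(2 * np.pi * 5.0 * t)
            data[ci, i0:i1] += seg

        # implant events: SOs first so spindles can couple to them
        so_by_time: list[tuple[float, float, float]] = []  # start, d_n, d_p
        occupied_by_class: dict[str, list] = {}
        ordered = sorted((s for s in specs if ch in s.resolved_channels),
                         key=lambda s: 0 if s.event_class == "so" else 1)
        for spec in ordered:
            segments = _stage_segments(hypnogram, spec.stages)
            occ = occupied_by_class.setdefault(spec.event_class, [])
            if spec.event_class == "so":
                intervals = _place_events(spec, segments, occ, rng)
                d_n, d_p = _so_split(spec.duration)
                p2p = spec.p2p if spec.p2p is not None else 1.6 * spec.amplitude
                for start, stop in intervals:
                    amp = spec.amplitude
                    if spec.amp_jitter_cv > 0:
                        sig = np.sqrt(np.log1p(spec.amp_jitter_cv**2))
                        amp = amp * rng.lognormal(-sig**2 / 2, sig)
                    wave = so_waveform(fs, d_n, d_p, amp, p2p * amp / spec.amplitude)
                    i0 = int(round(start * fs))
                    data[ci, i0:i0 + len(wave)] += wave[:n_samples - i0]
                    so_by_time.append((start, d_n, d_p))
                    event_rows.append(dict(
                        event_class="so", channel=ch, start_s=start,
                        stop_s=start + d_n + d_p,
                        peak_s=start + d_n / 2.0,           # negative peak
                        phase_at_peak_deg=180.0,
                        amplitude=amp, duration=d_n + d_p,
                        frequency=np.nan, chirp=np.nan))
                occ.extend(intervals)
            else:
                coupled = spec.coupling_kappa > 0 and len(so_by_time) > 0
                if coupled:
                    intervals = _place_coupled_spindles(
                        spec, so_by_time, segments, occ, hypnogram, rng)
                else:
                    intervals = [(a, b, np.nan) for a, b in
                                 _place_events(spec, segments, occ, rng)]
                for start, stop, phase in intervals:
                    amp, freq = spec.amplitude, spec.frequency
                    if spec.amp_jitter_cv > 0:
                        sig = np.sqrt(np.log1p(spec.amp_jitter_cv**2))
                        amp = amp * rng.lognormal(-sig**2 / 2, sig)
                    if spec.freq_jitter_sd > 0:
                        freq = freq + rng.normal(0, spec.freq_jitter_sd)
                    wave = spindle_waveform(fs, spec.duration, freq, spec.chirp,
                                            amp, phase0=rng.uniform(0, 2 * np.pi))
                    i0 = int(round(start * fs))
                    data[ci, i0:i0 + len(wave)] += wave[:n_samples - i0]
                    event_rows.append(dict(
                        event_class=spec.event_class, channel=ch,
                        start_s=start, stop_s=stop,
                        peak_s=start + spec.duration / 2.0,
                        phase_at_peak_deg=phase,
                        amplitude=amp, duration=spec.duration,
                        frequency=freq, chirp=spec.chirp))
                occ.extend([(a, b) for a, b, _ in intervals])

    events = pd.DataFrame(event_rows, columns=[
        "event_class", "channel", "start_s", "stop_s", "peak_s",
        "phase_at_peak_deg", "amplitude", "duration", "frequency", "chirp"])
    gt = GroundTruth(
        events=events.sort_values(["channel", "start_s"]).reset_index(drop=True),
        artifact_log=pd.DataFrame(columns=["channel", "epoch_index", "kind"]),
        true_features={"subject_id": profile.subject_id, "age": profile.age},
    )
    rec = Recording(channels, data, float(fs),
                    reference={ch: "raw" for ch in channels})
    return rec, gt


def _runs(stages: np.ndarray):
    """Maximal constant-stage runs as (label, first_epoch, last_epoch+1)."""
    out = []
    start = 0
    for i in range(1, len(stages) + 1):
        if i == len(stages) or stages[i] != stages[start]:
            out.append((stages[start], start, i))
            start = i
    return out


def _place_coupled_spindles(spec: EventSpec, sos: list, segments: list,
                            existing: list, hyp: Hypnogram,
                            rng: np.random.Generator,
                            min_gap: float = 1.0, max_tries: int = 5000):
    """Place spindle peaks at von Mises-drawn SO phases.

    Returns a list of (start, stop, phase_deg).
    """
    minutes = sum(b - a for a, b in segments) / 60.0
    n_events = int(round(spec.density * minutes))
    placed = []
    occupied = list(existing)
    half = spec.duration / 2.0
    for _ in range(n_events):
        for attempt in range(max_tries):
            k = int(rng.integers(len(sos)))
            so_start, d_n, d_p = sos[k]
            phase = np.degrees(rng.vonmises(np.radians(spec.coupling_phase),
                                            spec.coupling_kappa)) % 360.0
            peak = so_phase_to_time(phase, so_start, d_n, d_p)
            start, stop = peak - half, peak + half
            if start < 0 or any(not (stop + min_gap <= s or start - min_gap >= e)
                                for s, e in occupied):
                continue
            if _inside_segments(start, stop, segments):
                placed.append((start, stop, phase))
                occupied.append((start, stop))
                break
        else:
            raise ValueError(
                f"coupled density {spec.density}/min infeasible for available "
                f"{'/'.join(spec.stages)} time")
    return placed


def _inside_segments(start: float, stop: float, segments: list) -> bool:
    return any(a <= start and stop <= b for a, b in segments)


# ---------------------------------------------------------------------------
# artifacts
# ---------------------------------------------------------------------------

ARTIFACT_KINDS = ("clip", "flatline", "high_amplitude", "line60", "polarity_flip")


def inject_artifacts(recording: Recording, artifact_spec: list[dict],
                     seed: int = 0) -> tuple[Recording, pd.DataFrame]:
    """Apply logged artifacts to specific (channel, epoch) targets.

    Each spec item is a dict with keys ``kind``, ``channel`` and (except
    for ``polarity_flip``) ``epoch``.  Optional keys: ``fraction`` (flat
    or clipped portion of the epoch, default 1.0 for flatline / 0.4 for
    clip), ``amplitude`` (µV; pulse height for high_amplitude, sinusoid
    amplitude for line60).
    """
    rec = recording.copy()
    fs = rec.fs
    epoch_n = int(round(EPOCH_SECONDS * fs))
    log = []
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for item in artifact_spec:
        kind = item["kind"]
        if kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {kind!r}")
        ch = item["channel"]
        ci = rec.channels.index(ch)
        if kind == "polarity_flip":
            rec.data[ci] *= -1.0
            log.append({"channel": ch, "epoch_index": -1, "kind": kind})
            continue
        ep = int(item["epoch"])
        i0, i1 = ep * epoch_n, min((ep + 1) * epoch_n, rec.n_samples)
        seg = rec.data[ci, i0:i1]
        if kind == "high_amplitude":
            amp = float(item.get("amplitude", 300.0))
            n = min(int(fs), len(seg))
            pulse = amp * np.sin(np.pi * np.arange(n) / n) ** 2
            off = int(rng.integers(0, max(1, len(seg) - n)))
            seg[off:off + n] += pulse
        elif kind == "flatline":
            frac = float(item.get("fraction", 1.0))
            n = int(frac * len(seg))
            off = int(rng.integers(0, max(1, len(seg) - n + 1)))
            seg[off:off + n] = seg[off] if n else 0.0
        elif kind == "clip":
            frac = float(item.get("fraction", 0.4))
            level = np.quantile(np.abs(seg), 1.0 - frac)
            np.clip(seg, -level, level, out=seg)
        elif kind == "line60":
            amp = float(item.get("amplitude", 20.0))
            t = np.arange(i0, i1) / fs
            seg += amp * np.sin(2 * np.pi * 60.0 * t)
        log.append({"channel": ch, "epoch_index": ep, "kind": kind})
    return rec, pd.DataFrame(log, columns=["channel", "epoch_index", "kind"])


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortParams:
    """Age-structured cohort with per-subject developmental offsets.

    ``curves`` maps feature name -> f(age) giving the population-mean
    trajectory.  Each subject carries a latent ``trajectory_offset``
    drawn N(0, offset_sd) — a shared developmental delay/advance that
    moves *all* of their features along the age axis — plus independent
    per-feature measurement noise.  Named groups evaluate the curves at
    age + group offset, emulating delayed (negative) or advanced
    development.
    """

    n: int = 200
    age_range: tuple = (2.5, 17.5)
    curves: dict = field(default_factory=dict)
    offset_sd: float = 1.0            # years, subject-level developmental noise
    feature_noise_sd: float = 0.05    # SD of per-feature noise, in curve units
    groups: dict = field(default_factory=dict)  # name -> dict(n=, offset=, age_range=)

    def validate(self) -> None:
        if self.n < 10:
            raise ValueError("cohort n must be >= 10")
        if not self.curves:
            raise ValueError("at least one trajectory curve is required")


def simulate_cohort(params: CohortParams, seed: int = 0):
    """Draw a cohort of subjects and evaluate feature trajectories.

    Returns (features, subjects, truth): a subject x feature DataFrame,
    a subject table (age, sex, race, group, ahi, medication), and a
    GroundTruth whose ``true_features`` holds the noise-free curve
    values and latent offsets.
    """
    params.validate()
    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)

    rows, feats, clean = [], [], []
    cohorts = [("non-NDD", params.n, 0.0, params.age_range)]
    for name, g in params.groups.items():
        cohorts.append((name, g["n"], g.get("offset", 0.0),
                        g.get("age_range", params.age_range)))

    idx = 0
    for gname, n, goffset, arange in cohorts:
        for _ in range(n):
            age = rng.uniform(*arange)
            subj_off = rng.normal(0.0, params.offset_sd) if params.offset_sd > 0 else 0.0
            eff_age = age + goffset + subj_off
            row = {}
            truth_row = {}
            for feat, curve in params.curves.items():
                mu = float(curve(eff_age))
                if not np.isfinite(mu):
                    raise ValueError(f"curve {feat!r} undefined at age {eff_age:.2f}")
                noise = (rng.normal(0.0, params.feature_noise_sd)
                         if params.feature_noise_sd > 0 else 0.0)
                row[feat] = mu + noise
                truth_row[feat] = float(curve(age + goffset))
            rows.append({
                "subject_id": f"S{idx:04d}", "age": age,
                "sex": "F" if rng.random() < 0.5 else "M",
                "race": rng.choice(["white", "black", "other"], p=[0.64, 0.22, 0.14]),
                "group": gname,
                "ahi": float(rng.lognormal(0.0, 0.8)),
                "medication": bool(rng.random() < 0.14),
                "trajectory_offset": goffset + subj_off,
            })
            feats.append(row)
            clean.append(truth_row)
            idx += 1

    subjects = pd.DataFrame(rows).set_index("subject_id", drop=False)
    subjects.index.name = None
    features = pd.DataFrame(feats, index=subjects.index)
    truth = GroundTruth(
        events=pd.DataFrame(),
        artifact_log=pd.DataFrame(columns=["channel", "epoch_index", "kind"]),
        true_features={
            "clean": pd.DataFrame(clean, index=subjects["subject_id"]),
            "offsets": subjects.set_index("subject_id")["trajectory_offset"],
        },
    )
    return features, subjects, truth
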