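"""End-to-end validation experiments on synthetic ground truth.

Each function builds a synthetic scenario with known truth, runs the
corresponding pipeline stage from scratch, and returns the measured
performance numbers (recall, calibration rates, recovery errors).
They back both the acceptance test suite and ``scripts/acceptance.py``.

Problem sizes are chosen so the full battery completes in a few
minutes on one core while keeping Monte-Carlo error well inside the
tolerances being checked; each docstring states the sizes used.
"""

from __future__ import annotations

import time

import numpy as np

from .brainage import fit_brain_age, gap_group_analysis, select_features
from .coupling import couple, permutation_null, so_phase
from .hypnogram import Hypnogram
from .preprocess import epoch_record, hjorth
from .so import SOThresholds, detect_so
from .spectral import band_powers, welch_psd
from .spindles import detect_channel_spindles, spindle_metrics
from .synth import (
    CohortParams, EventSpec, NoiseParams, SubjectProfile, simulate_cohort,
    synthesize_record,
)

FS = 200.0


def _n2(n_epochs: int) -> Hypnogram:
    return Hypnogram(np.array(["N2"] * n_epochs, dtype=object))


# ---------------------------------------------------------------------------
# spindle detection and morphology
# ---------------------------------------------------------------------------


def spindle_detection_benchmark(n_records: int = 20, seed: int = 0,
                                minutes: float = 30.0) -> dict:
    """Recall/precision/density error over a 0.5-3 per-minute grid.

    ``n_records`` synthetic N2 records (default 30 min each) carry fast
    spindles at 30 µV (an order of magnitude above the ~2.5 µV
    sigma-band background RMS, comfortably past the detectability
    floor).  A detection matches truth when peaks agree within 0.25 s.
    """
    densities = np.linspace(0.5, 3.0, n_records)
    recalls, precisions, density_errors, runtimes, chirps = [], [], [], [], []
    hyp = _n2(int(minutes * 2))
    for i in range(n_records):
        spec = EventSpec("fast_spindle", density=float(densities[i]),
                         amplitude=30.0, duration=1.0, frequency=15.0,
                         channels=("C3",))
        rec, gt = synthesize_record(SubjectProfile("s", 10.0), hyp, [spec],
                                    fs=FS, seed=seed * 1000 + i,
                                    channels=["C3"])
        t0 = time.perf_counter()
        ep = epoch_record(rec, hyp)
        events = [e for e in detect_channel_spindles(ep, "C3", "fast")
                  if e.qc_pass]
        runtimes.append(time.perf_counter() - t0)
        peaks = np.array([e.peak_time_s for e in events])
        truth = gt.events["peak_s"].to_numpy()
        if len(peaks) == 0 or len(truth) == 0:
            recalls.append(0.0)
            precisions.append(0.0)
            continue
        tp_truth = sum(np.min(np.abs(peaks - p)) <= 0.25 for p in truth)
        tp_det = sum(np.min(np.abs(truth - p)) <= 0.25 for p in peaks)
        recalls.append(tp_truth / len(truth))
        precisions.append(tp_det / len(peaks))
        m = spindle_metrics(events, ep.kept_minutes("N2", "C3"))
        density_errors.append(abs(m["density"] - densities[i]) / densities[i])
        chirps += [e.chirp_hz for e in events]
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "density_error_pct": float(100 * np.mean(density_errors)),
        "max_runtime_s": float(np.max(runtimes)),
        "chirp_constant_mean": float(np.mean(chirps)),
        "n_constant_chirp_events": len(chirps),
    }


def chirp_recovery_benchmark(n_records: int = 8, seed: int = 1) -> dict:
    """Mean estimated chirp for implanted -1.0 Hz intra-event ramps.

    Pools ~60 events per record over ``n_records`` 30-min N2 records;
    the half-difference construction should recover -0.5 Hz.
    """
    hyp = _n2(60)
    chirps = []
    for i in range(n_records):
        spec = EventSpec("fast_spindle", density=2.0, amplitude=30.0,
                         duration=1.0, frequency=15.0, chirp=-1.0,
                         channels=("C3",))
        rec, _ = synthesize_record(SubjectProfile("s", 10.0), hyp, [spec],
                                   fs=FS, seed=seed * 1000 + i,
                                   channels=["C3"])
        ep = epoch_record(rec, hyp)
        chirps += [e.chirp_hz for e in
                   detect_channel_spindles(ep, "C3", "fast") if e.qc_pass]
    return {"chirp_ramp_mean": float(np.mean(chirps)), "n_events": len(chirps)}


# ---------------------------------------------------------------------------
# coupling calibration
# ---------------------------------------------------------------------------


def _coupling_run(seed: int, kappa: float, perm_seed: int,
                  n_perm: int = 2000, n_epochs: int = 120):
    """One synthetic N2 hour: implant SOs (+ coupled or uncoupled
    spindles), detect SOs, and permutation-test the coupling of the
    ground-truth spindle peaks."""
    hyp = _n2(n_epochs)
    specs = [EventSpec("so", density=8.0, amplitude=80.0, p2p=130.0,
                       duration=1.2, channels=("C3",)),
             EventSpec("fast_spindle", density=3.0, amplitude=30.0,
                       duration=1.0, coupling_phase=0.0,
                       coupling_kappa=kappa, channels=("C3",))]
    rec, gt = synthesize_record(SubjectProfile("s", 8.0), hyp, specs,
                                fs=FS, seed=seed, channels=["C3"])
    x = rec.get("C3")
    phase = so_phase(x, FS)
    sos = detect_so(x, FS, SOThresholds(mode="absolute"))
    peaks = gt.events.query("event_class=='fast_spindle'")["peak_s"].to_numpy()
    res = couple(peaks, sos, phase, FS)
    return permutation_null(res, peaks, sos, phase, FS,
                            n_perm=n_perm, seed=perm_seed)


def coupling_null_calibration(n_runs: int = 300, n_perm: int = 2000,
                              seed: int = 2) -> dict:
    """z-score calibration under kappa=0 (no phase preference).

    300 runs keep the standard error of the mean z near 0.05, well
    inside the +/-0.2 calibration band being checked.
    """
    itpc_z, overlap_z = [], []
    for i in range(n_runs):
        r = _coupling_run(seed * 10000 + i, 0.0, seed * 20000 + i, n_perm)
        itpc_z.append(r.itpc_z)
        overlap_z.append(r.overlap_z)
    itpc_z = np.asarray(itpc_z)
    overlap_z = np.asarray(overlap_z)
    return {
        "itpc_z_mean": float(np.nanmean(itpc_z)),
        "itpc_z_exceed_rate": float(np.mean(np.abs(itpc_z) > 1.96)),
        "overlap_z_mean": float(np.nanmean(overlap_z)),
        "overlap_z_exceed_rate": float(np.mean(np.abs(overlap_z) > 1.96)),
        "n_runs": n_runs,
    }


def coupling_power(n_seeds: int = 20, seed: int = 3) -> dict:
    """Detection power for kappa=5 coupling with >= 50 overlapping
    spindles per run."""
    hits, overlaps = 0, []
    for i in range(n_seeds):
        r = _coupling_run(seed * 1000 + i, 5.0, seed * 2000 + i)
        overlaps.append(r.n_overlap)
        hits += r.itpc_z > 1.96
    return {"power": hits / n_seeds, "min_overlap": int(np.min(overlaps))}


def coupling_phase_recovery(n_seeds: int = 5, seed: int = 4,
                            kappa: float = 20.0) -> dict:
    """Recovery of a 0-degree coupling preference at kappa=20, via full
    spindle + SO detection.

    The recovered phase is the circular mean of the per-record coupling
    angles (pooling cancels per-record sampling scatter); the reported
    error is its angular distance from the implanted preference.
    """
    angles = []
    for i in range(n_seeds):
        hyp = _n2(40)
        specs = [EventSpec("so", density=6.0, amplitude=80.0, p2p=130.0,
                           duration=1.2, channels=("C3",)),
                 EventSpec("fast_spindle", density=2.0, amplitude=30.0,
                           duration=1.0, coupling_phase=0.0,
                           coupling_kappa=kappa, channels=("C3",))]
        rec, _ = synthesize_record(SubjectProfile("s", 8.0), hyp, specs,
                                   fs=FS, seed=seed * 1000 + i,
                                   channels=["C3"])
        x = rec.get("C3")
        phase = so_phase(x, FS)
        sos = detect_so(x, FS, SOThresholds(mode="absolute"))
        ep = epoch_record(rec, hyp)
        evs = [e for e in detect_channel_spindles(ep, "C3", "fast")
               if e.qc_pass]
        res = couple(np.array([e.peak_time_s for e in evs]), sos, phase, FS)
        angles.append(res.mean_angle_deg)
    z = np.exp(1j * np.radians(angles)).mean()
    pooled = np.degrees(np.angle(z))
    return {"phase_error_deg": float(abs((pooled + 180.0) % 360.0 - 180.0))}


# ---------------------------------------------------------------------------
# SO threshold-mode divergence
# ---------------------------------------------------------------------------


def so_mode_divergence(n_seeds: int = 10, seed: int = 5) -> dict:
    """Sign test of relative- vs absolute-mode density-age slopes.

    Nine synthetic subjects per cohort (ages 4-16, 36 min N2 each —
    a scale-down of the ~3 h of N2 in a real night that keeps the
    Poisson noise of per-subject density below the age effect) with SO
    amplitude and background EEG amplitude declining with age.
    """
    ages = np.linspace(4.0, 16.0, 9)
    rel_pos, abs_neg = 0, 0
    rel_slopes, abs_slopes = [], []
    for s in range(n_seeds):
        rel_d, abs_d = [], []
        for i, age in enumerate(ages):
            hyp = _n2(72)
            amp = 85.0 - 3.0 * (age - 4.0)
            noise = NoiseParams()
            noise.rms = dict(noise.rms)
            noise.rms["N2"] = 30.0 - 1.2 * (age - 4.0)
            spec = EventSpec("so", density=6.0, amplitude=amp, p2p=1.6 * amp,
                             duration=1.2, channels=("C3",),
                             amp_jitter_cv=0.2)
            rec, _ = synthesize_record(
                SubjectProfile("s", age), hyp, [spec], noise=noise, fs=FS,
                seed=seed * 10000 + s * 100 + i, channels=["C3"])
            x = rec.get("C3")
            rel_d.append(len(detect_so(x, FS, SOThresholds(mode="relative"))))
            abs_d.append(len(detect_so(x, FS, SOThresholds(mode="absolute"))))
        rel_slopes.append(np.polyfit(ages, rel_d, 1)[0])
        abs_slopes.append(np.polyfit(ages, abs_d, 1)[0])
        rel_pos += rel_slopes[-1] > 0
        abs_neg += abs_slopes[-1] < 0
    return {"relative_slope_positive": int(rel_pos),
            "absolute_slope_negative": int(abs_neg),
            "n_seeds": n_seeds,
            "relative_slope_mean": float(np.mean(rel_slopes)),
            "absolute_slope_mean": float(np.mean(abs_slopes))}


# ---------------------------------------------------------------------------
# spectral and Hjorth oracles
# ---------------------------------------------------------------------------


def spectral_oracle(seed: int = 6) -> dict:
    """Parseval agreement and exact scale equivariance."""
    t = np.arange(int(30 * FS)) / FS
    sine = np.tile(np.sqrt(2.0) * np.sin(2 * np.pi * 10.0 * t), (4, 1))
    f, p = welch_psd(sine, FS)
    sine_total = band_powers(f, p).loc["total", "absolute"]

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((30, int(30 * FS)))
    f, p = welch_psd(white, FS)
    white_total = band_powers(f, p).loc["total", "absolute"]

    f, p2 = welch_psd(3.0 * sine, FS)
    scale_err = abs(band_powers(f, p2).loc["total", "absolute"]
                    / (9.0 * sine_total) - 1.0)
    return {
        "parseval_sine_error_pct": float(100 * abs(sine_total - 1.0)),
        # white-noise variance inside 0.5-35 Hz = 34.5 % of total
        "parseval_noise_error_pct": float(100 * abs(white_total / 0.345 - 1.0)),
        "scale_equivariance_error": float(scale_err),
    }


def hjorth_oracle(seed: int = 7) -> dict:
    """Closed-form mobility for a sinusoid; unit-variance activity."""
    t = np.arange(6000) / FS
    _, mob, _, _ = hjorth(np.sin(2 * np.pi * 10.0 * t))
    expected = 2.0 * np.sin(np.pi * 10.0 / FS)
    rng = np.random.default_rng(seed)
    act, _, _, _ = hjorth(rng.standard_normal(6000))
    return {
        "mobility_error_pct": float(100 * abs(mob / expected - 1.0)),
        "activity_error_pct": float(100 * abs(act - 1.0)),
    }


# ---------------------------------------------------------------------------
# brain age
# ---------------------------------------------------------------------------


def _linear_curves(n_features: int = 40, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    curves = {}
    for j in range(n_features):
        a = rng.uniform(0.8, 1.2) * (-1 if j % 2 else 1)
        b = rng.uniform(-5.0, 5.0)
        curves[f"feat{j:02d}"] = (lambda a, b: (lambda age: a * age + b))(a, b)
    return curves


def brainage_benchmark(n_replicates: int = 10, seed: int = 8,
                       n_rounds: int = 100) -> dict:
    """Held-out error and delayed-group gap on synthetic cohorts.

    Each replicate: n=600 non-NDD subjects (ages 2.5-17.5), 40 linear
    age-tracking features, 1-yr latent developmental noise (the
    irreducible residual), plus a fixed n=50 group generated 2 years
    delayed.  Per-feature measurement noise (SD 1.75 in curve units) is
    small enough that averaging over 40 features leaves the residual SD
    near the 1-yr latent target (~1.04).  The resampled group analysis
    (70/30 resplits) runs on the first replicate.
    """
    held_mae, held_me, delayed_me, delayed_mae = [], [], [], []
    median_p = np.nan
    for r in range(n_replicates):
        params = CohortParams(
            n=600, age_range=(2.5, 17.5), curves=_linear_curves(),
            offset_sd=1.0, feature_noise_sd=1.75,
            groups={"delayed": {"n": 50, "offset": -2.0}})
        features, subjects, _ = simulate_cohort(params, seed=seed * 100 + r)
        idx = subjects.index[subjects["group"] == "non-NDD"]
        perm = np.random.default_rng(seed * 200 + r).permutation(len(idx))
        n_train = int(round(0.7 * len(idx)))
        tr, te = idx[perm[:n_train]], idx[perm[n_train:]]
        feats = select_features(features.loc[tr])
        model = fit_brain_age(features.loc[tr], subjects.loc[tr],
                              feature_list=feats, n_folds=0)
        held = model.predict(features.loc[te], subjects.loc[te])
        d = subjects["group"] == "delayed"
        grp = model.predict(features[d], subjects[d])
        held_mae.append(held.mae)
        held_me.append(held.me)
        delayed_me.append(grp.me)
        delayed_mae.append(grp.mae)
        if r == 0:
            gap = gap_group_analysis(features, subjects, n_rounds=n_rounds,
                                     seed=seed)
            median_p = float(gap.set_index("group")
                             .loc["delayed", "median_p_me"])
    return {
        "held_out_mae": float(np.mean(held_mae)),
        "held_out_me": float(np.mean(held_me)),
        "delayed_me": float(np.mean(delayed_me)),
        "delayed_mae": float(np.mean(delayed_mae)),
        "delayed_median_p": median_p,
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def determinism_check(seed: int = 9) -> dict:
    """Same parameters + seed must reproduce signals, events and
    detections exactly."""
    hyp = _n2(20)
    specs = [EventSpec("so", density=6.0, amplitude=80.0, p2p=130.0,
                       duration=1.2, channels=("C3",)),
             EventSpec("fast_spindle", density=2.0, channels=("C3",))]

    def run():
        rec, gt = synthesize_record(SubjectProfile("s", 9.0), hyp, specs,
                                    fs=FS, seed=seed, channels=["C3"])
        ep = epoch_record(rec, hyp)
        evs = detect_channel_spindles(ep, "C3", "fast")
        sos = detect_so(rec.get("C3"), FS, SOThresholds(mode="absolute"))
        return rec, gt, evs, sos

    r1, g1, e1, s1 = run()
    r2, g2, e2, s2 = run()
    ok = (np.array_equal(r1.data, r2.data)
          and g1.events.equals(g2.events)
          and [e.__dict__ for e in e1] == [e.__dict__ for e in e2]
          and [s.__dict__ for s in s1] == [s.__dict__ for s in s2])
    return {"deterministic": int(ok)}
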