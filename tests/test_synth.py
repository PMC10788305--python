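"""Synthetic PSG generator: bookkeeping, determinism, waveform identities."""

import numpy as np
import pandas as pd
import pytest

from psgkit import (
    EventSpec, SubjectProfile, inject_artifacts, simulate_cohort,
    synthesize_record,
)
from psgkit.coupling import circular_mean_deg
from psgkit.synth import (
    CohortParams, spindle_waveform, so_waveform, so_phase_to_time,
)
from conftest import n2_hypnogram

FS = 200.0


class TestEventBookkeeping:
    def test_exact_event_count_from_density(self):
        hyp = n2_hypnogram(200)  # 100 min N2
        spec = EventSpec("fast_spindle", density=2.0, channels=("C3",))
        _, gt = synthesize_record(SubjectProfile("s", 10), hyp, [spec],
                                  fs=FS, seed=0, channels=["C3"])
        assert len(gt.events) == 200

    def test_events_lie_within_record_and_are_disjoint(self):
        hyp = n2_hypnogram(40)
        spec = EventSpec("fast_spindle", density=3.0, channels=("C3",))
        _, gt = synthesize_record(SubjectProfile("s", 10), hyp, [spec],
                                  fs=FS, seed=1, channels=["C3"])
        ev = gt.events.sort_values("start_s")
        assert (ev["stop_s"] <= hyp.duration_s).all()
        assert (ev["start_s"].to_numpy()[1:] >= ev["stop_s"].to_numpy()[:-1]).all()

    def test_infeasible_density_raises_naming_stage(self):
        hyp = n2_hypnogram(4)  # 2 min N2
        spec = EventSpec("fast_spindle", density=60.0, channels=("C3",))
        with pytest.raises(ValueError, match="N2"):
            synthesize_record(SubjectProfile("s", 10), hyp, [spec],
                              fs=FS, seed=0, channels=["C3"])

    def test_determinism_bit_identical(self):
        hyp = n2_hypnogram(20)
        specs = [EventSpec("fast_spindle", density=2.0, channels=("C3",))]
        r1, g1 = synthesize_record(SubjectProfile("s", 10), hyp, specs,
                                   fs=FS, seed=3, channels=["C3"])
        r2, g2 = synthesize_record(SubjectProfile("s", 10), hyp, specs,
                                   fs=FS, seed=3, channels=["C3"])
        assert np.array_equal(r1.data, r2.data)
        pd.testing.assert_frame_equal(g1.events, g2.events)

    def test_zero_noise_signal_equals_analytic_waveform(self):
        from psgkit.synth import NoiseParams
        hyp = n2_hypnogram(4)
        spec = EventSpec("fast_spindle", density=0.5, amplitude=30.0,
                         duration=1.0, frequency=15.0, channels=("C3",))
        noise = NoiseParams(rms={"N2": 0.0}, alpha={"N2": 1.5},
                            wake_alpha_uv=0.0, rem_theta_uv=0.0,
                            mastoid_rms=0.0)
        rec, gt = synthesize_record(SubjectProfile("s", 10), hyp, [spec],
                                    noise=noise, fs=FS, seed=2,
                                    channels=["C3"])
        ev = gt.events.iloc[0]
        i0 = int(round(ev["start_s"] * FS))
        n = int(round(ev["duration"] * FS))
        seg = rec.get("C3")[i0:i0 + n]
        # envelope of the implanted event must match the Hann template
        assert np.max(np.abs(seg)) == pytest.approx(30.0, rel=0.02)
        outside = np.concatenate([rec.get("C3")[:i0], rec.get("C3")[i0 + n:]])
        assert np.max(np.abs(outside)) < 1e-9

    def test_coupled_phases_concentrate_at_requested_angle(self):
        hyp = n2_hypnogram(40)
        specs = [
            EventSpec("so", density=6.0, amplitude=80, p2p=130, duration=1.2,
                      channels=("C3",)),
            EventSpec("fast_spindle", density=2.0, coupling_phase=0.0,
                      coupling_kappa=50.0, channels=("C3",)),
        ]
        _, gt = synthesize_record(SubjectProfile("s", 8), hyp, specs,
                                  fs=FS, seed=4, channels=["C3"])
        phases = gt.events.query("event_class=='fast_spindle'")[
            "phase_at_peak_deg"].to_numpy()
        mean = circular_mean_deg(phases)
        assert min(mean, 360 - mean) < 5.0


class TestWaveforms:
    def test_spindle_envelope_is_hann_with_requested_peak(self):
        w = spindle_waveform(FS, 1.0, 13.0, 0.0, 25.0)
        assert len(w) == 200
        assert np.max(np.abs(w)) <= 25.0 + 1e-9

    def test_so_waveform_peaks_and_p2p(self):
        w = so_waveform(FS, 0.6, 0.5, 80.0, 130.0)
        assert w.min() == pytest.approx(-80.0, rel=1e-6)
        assert w.max() == pytest.approx(50.0, rel=1e-6)

    def test_phase_to_time_anchors(self):
        # negative peak (180 deg) at the middle of the negative half-wave
        t = so_phase_to_time(180.0, start=10.0, neg_duration=0.6,
                             pos_duration=0.5)
        assert t == pytest.approx(10.3)
        # positive peak (0 deg) at the middle of the positive half-wave
        t = so_phase_to_time(0.0, start=10.0, neg_duration=0.6,
                             pos_duration=0.5)
        assert t == pytest.approx(10.85)


class TestInjectArtifacts:
    def test_empty_spec_is_identity(self, spindle_record):
        rec, _, _ = spindle_record
        out, log = inject_artifacts(rec, [], seed=0)
        assert np.array_equal(out.data, rec.data)
        assert len(log) == 0

    def test_polarity_flip_negates_whole_channel(self, spindle_record):
        rec, _, _ = spindle_record
        out, log = inject_artifacts(
            rec, [{"kind": "polarity_flip", "channel": "C3"}], seed=0)
        assert np.array_equal(out.get("C3"), -rec.get("C3"))

    def test_artifacts_confined_to_logged_epochs(self, spindle_record):
        rec, _, _ = spindle_record
        out, log = inject_artifacts(
            rec, [{"kind": "flatline", "channel": "C3", "epoch": 5}], seed=0)
        n = int(30 * FS)
        changed = np.flatnonzero(out.get("C3") != rec.get("C3"))
        assert changed.size and changed.min() >= 5 * n and changed.max() < 6 * n

    def test_unknown_kind_raises(self, spindle_record):
        rec, _, _ = spindle_record
        with pytest.raises(ValueError, match="unknown artifact kind"):
            inject_artifacts(rec, [{"kind": "gremlin", "channel": "C3",
                                    "epoch": 0}], seed=0)


class TestSimulateCohort:
    def curves(self):
        return {"fs_density": lambda age: 0.9 + 0.083 * (age - 4.0),
                "theta_power": lambda age: 120.0 - 4.0 * age}

    def test_linear_curve_evaluated_at_endpoint_ages(self):
        # fast-spindle density 0.9/min at age 4 rising to 1.9/min at 16
        c = self.curves()["fs_density"]
        assert c(4.0) == pytest.approx(0.9)
        assert c(16.0) == pytest.approx(1.896, abs=0.01)

    def test_zero_noise_reproduces_curves_exactly(self):
        params = CohortParams(n=20, age_range=(4, 16), curves=self.curves(),
                              offset_sd=0.0, feature_noise_sd=0.0)
        feats, subs, truth = simulate_cohort(params, seed=0)
        expected = np.array([self.curves()["fs_density"](a)
                             for a in subs["age"]])
        np.testing.assert_allclose(feats["fs_density"].to_numpy(), expected)

    def test_delayed_group_matches_younger_subjects(self):
        params = CohortParams(
            n=20, age_range=(6, 16), curves=self.curves(),
            offset_sd=0.0, feature_noise_sd=0.0,
            groups={"delayed": {"n": 10, "offset": -2.0}})
        feats, subs, truth = simulate_cohort(params, seed=1)
        d = subs["group"] == "delayed"
        expected = np.array([self.curves()["fs_density"](a - 2.0)
                             for a in subs.loc[d, "age"]])
        np.testing.assert_allclose(feats.loc[d, "fs_density"], expected)

    def test_undefined_curve_raises(self):
        def partial(age):
            if age > 10:
                return np.nan
            return age
        params = CohortParams(n=20, age_range=(4, 16),
                              curves={"f": partial}, offset_sd=0.0)
        with pytest.raises(ValueError, match="undefined"):
            simulate_cohort(params, seed=0)

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            CohortParams(n=5, curves={"f": lambda a: a}).validate()
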