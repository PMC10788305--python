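"""Preprocessing: filters, Hjorth closed forms, rejection rules, polarity."""

import numpy as np
import pytest
from scipy import signal as sps

from psgkit import (
    EventSpec, SubjectProfile, synthesize_record, preprocess,
    PreprocessConfig, epoch_record, reject_artifacts, resolve_polarity,
    apply_record_exclusions, hjorth, inject_artifacts, bandpass_filter,
    remove_line_noise, t_diff,
)
from psgkit.preprocess import RejectionThresholds
from psgkit.recording import Recording
from conftest import n2_hypnogram

FS = 200.0


class TestFilters:
    def test_line_noise_removed_by_spectrum_interpolation(self):
        rng = np.random.default_rng(0)
        t = np.arange(int(120 * FS)) / FS
        x = 10 * rng.standard_normal(t.size) + 20 * np.sin(2 * np.pi * 60 * t)
        y = remove_line_noise(x, FS, 60.0)
        f, p0 = sps.welch(x, FS, nperseg=int(4 * FS))
        _, p1 = sps.welch(y, FS, nperseg=int(4 * FS))
        band = (f >= 59.5) & (f <= 60.5)
        assert p1[band].sum() < 0.1 * p0[band].sum()
        # broadband power elsewhere untouched
        rest = (f > 5) & (f < 50)
        assert p1[rest].sum() == pytest.approx(p0[rest].sum(), rel=0.02)

    def test_dc_offset_removed_by_highpass(self):
        x = np.full(int(60 * FS), 100.0)
        rec = Recording(["C3"], x[None, :], FS)
        out = preprocess(rec, PreprocessConfig(reference=False,
                                               remove_mains=False))
        assert abs(out.get("C3").mean()) < 1.0

    def test_resampling_to_200hz_preserves_duration(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(int(30 * 256))
        rec = Recording(["C3"], x[None, :], 256.0)
        out = preprocess(rec, PreprocessConfig(reference=False))
        assert out.fs == 200.0
        assert abs(out.n_samples - 30 * 200) <= 1

    def test_zero_phase_filter_preserves_so_peak_time(self):
        from psgkit.synth import so_waveform
        x = np.zeros(int(60 * FS))
        w = so_waveform(FS, 0.7, 0.5, 80.0, 130.0)
        i0 = int(30 * FS)
        x[i0:i0 + len(w)] = w
        xf = bandpass_filter(x, FS, 0.5, 4.0)
        # forward-backward filtering must not shift the negative peak
        assert abs(int(np.argmin(xf)) - int(np.argmin(x))) <= 1

    def test_missing_mastoid_raises(self):
        rec = Recording(["C3"], np.zeros((1, int(35 * FS))), FS)
        with pytest.raises(ValueError, match="mastoid"):
            preprocess(rec, PreprocessConfig())


class TestHjorth:
    def test_sinusoid_mobility_closed_form(self):
        t = np.arange(6000) / FS
        _, mob, _, _ = hjorth(np.sin(2 * np.pi * 10 * t))
        assert mob == pytest.approx(2 * np.sin(np.pi * 10 / FS), rel=0.01)

    def test_white_noise_activity_near_unit_variance(self):
        x = np.random.default_rng(0).standard_normal(6000)
        act, _, _, _ = hjorth(x)
        assert act == pytest.approx(1.0, abs=0.1)

    def test_constant_signal_degenerate(self):
        act, mob, comp, degen = hjorth(np.full(100, 3.0))
        assert (act, mob, comp, degen) == (0.0, 0.0, 0.0, True)

    def test_too_short_input_raises(self):
        with pytest.raises(ValueError):
            hjorth(np.array([1.0, 2.0]))


class TestRejection:
    def _clean(self, seed, n_epochs=20):
        hyp = n2_hypnogram(n_epochs)
        rec, _ = synthesize_record(SubjectProfile("s", 8), hyp, [],
                                   fs=FS, seed=seed, include_mastoids=False)
        return rec, hyp

    def test_amplitude_spike_flagged(self):
        rec, hyp = self._clean(0, 12)
        rec2, _ = inject_artifacts(rec, [{"kind": "high_amplitude",
                                          "channel": "C3", "epoch": 7,
                                          "amplitude": 260}], seed=0)
        ep = reject_artifacts(epoch_record(rec2, hyp))
        row = ep.qc[(ep.qc["epoch"] == 7) & (ep.qc["channel"] == "C3")]
        assert not row["kept"].item()
        assert "max_amp" in row["reasons"].item()

    def test_flatline_over_ten_percent_flagged(self):
        rec, hyp = self._clean(1, 12)
        rec2, _ = inject_artifacts(rec, [{"kind": "flatline", "channel": "C4",
                                          "epoch": 3, "fraction": 0.15}], seed=0)
        ep = reject_artifacts(epoch_record(rec2, hyp))
        row = ep.qc[(ep.qc["epoch"] == 3) & (ep.qc["channel"] == "C4")]
        assert not row["kept"].item()
        assert "flat_clip" in row["reasons"].item()

    def test_clipping_flagged(self):
        rec, hyp = self._clean(2, 12)
        rec2, _ = inject_artifacts(rec, [{"kind": "clip", "channel": "F3",
                                          "epoch": 4, "fraction": 0.3}], seed=0)
        ep = reject_artifacts(epoch_record(rec2, hyp))
        row = ep.qc[(ep.qc["epoch"] == 4) & (ep.qc["channel"] == "F3")]
        assert not row["kept"].item()

    def test_fully_flat_channel_dropped(self):
        rec, hyp = self._clean(3, 12)
        rec.data[rec.channels.index("O1")] = 0.0
        ep = reject_artifacts(epoch_record(rec, hyp))
        assert "O1" in ep.dropped_channels.get("N2", [])

    def test_clean_record_false_positive_budget(self):
        # 3/4-SD Hjorth rules on clean records: < 8 % of epochs flagged
        rates = []
        for seed in range(10):
            rec, hyp = self._clean(100 + seed, 20)
            ep = reject_artifacts(epoch_record(rec, hyp))
            q = ep.qc[ep.qc["stage"] == "N2"]
            rates.append(1.0 - q["kept"].mean())
        assert np.mean(rates) < 0.08

    def test_rejection_idempotent(self):
        rec, hyp = self._clean(4, 16)
        rec.data[2, 5 * 6000:6 * 6000] += 100 * np.sin(
            2 * np.pi * 10 * np.arange(6000) / FS)
        ep1 = reject_artifacts(epoch_record(rec, hyp))
        flagged1 = set(map(tuple, ep1.qc[~ep1.qc["kept"]][
            ["epoch", "channel"]].to_numpy()))
        ep2 = reject_artifacts(ep1)
        flagged2 = set(map(tuple, ep2.qc[~ep2.qc["kept"]][
            ["epoch", "channel"]].to_numpy()))
        assert flagged2 == flagged1

    def test_mask_monotone_in_amplitude_threshold(self):
        rec, hyp = self._clean(5, 12)
        strict = reject_artifacts(epoch_record(rec, hyp),
                                  RejectionThresholds(max_amp_uv=60.0))
        lax = reject_artifacts(epoch_record(rec, hyp),
                               RejectionThresholds(max_amp_uv=200.0))
        flagged_lax = set(map(tuple, lax.qc[lax.qc["reasons"].str.contains(
            "max_amp")][["epoch", "channel"]].to_numpy()))
        flagged_strict = set(map(tuple, strict.qc[strict.qc["reasons"].str.contains(
            "max_amp")][["epoch", "channel"]].to_numpy()))
        assert flagged_lax <= flagged_strict


class TestPolarity:
    def _so_epoched(self, seed, negate=False):
        hyp = n2_hypnogram(30)
        specs = [EventSpec("so", density=8.0, amplitude=80, p2p=130,
                           duration=1.2, channels=("C3", "C4"))]
        rec, _ = synthesize_record(SubjectProfile("s", 6), hyp, specs,
                                   fs=FS, seed=seed, include_mastoids=False)
        if negate:
            rec.data *= -1.0
        return epoch_record(rec, hyp)

    def test_physiologic_record_classified_normal(self):
        assert resolve_polarity(self._so_epoched(0))["decision"] == "normal"

    def test_negated_record_classified_flipped(self):
        assert resolve_polarity(self._so_epoched(0, negate=True))[
            "decision"] == "flipped"

    def test_statistic_is_odd(self):
        ep = self._so_epoched(1)
        ep_neg = self._so_epoched(1, negate=True)
        assert t_diff(ep, "C3") == pytest.approx(-t_diff(ep_neg, "C3"))

    def test_symmetric_noise_is_ambiguous(self):
        hyp = n2_hypnogram(30)
        amb = 0
        for seed in range(20):
            rec, _ = synthesize_record(SubjectProfile("s", 6), hyp, [],
                                       fs=FS, seed=seed,
                                       include_mastoids=False)
            amb += resolve_polarity(epoch_record(rec, hyp))[
                "decision"] == "ambiguous"
        assert amb >= 18  # >= 90 %

    def test_insufficient_n2_defaults_to_ambiguous(self):
        hyp = n2_hypnogram(5)
        rec, _ = synthesize_record(SubjectProfile("s", 6), hyp, [],
                                   fs=FS, seed=0, include_mastoids=False)
        assert resolve_polarity(epoch_record(rec, hyp))[
            "decision"] == "ambiguous"


class TestExclusions:
    def test_short_tst_excluded(self):
        rep = apply_record_exclusions(179.0, {"N2": 100, "N3": 50, "R": 30})
        assert not rep.record_kept and "tst_lt_180" in rep.reasons

    def test_too_few_stage_epochs_excluded(self):
        rep = apply_record_exclusions(400.0, {"N2": 300, "N3": 100, "R": 9})
        assert "stage_epochs_lt_10" in rep.reasons

    def test_all_rules_pass_keeps_record(self):
        rep = apply_record_exclusions(
            400.0, {"N2": 300, "N3": 100, "R": 50},
            polarity={"decision": "normal"},
            spk_z={"C3": 0.5}, power_1hz_z={"C3": 1.0},
            power_25hz_z={"C3": -0.2})
        assert rep.record_kept and rep.reasons == []

    def test_cohort_rules(self):
        rep = apply_record_exclusions(
            400.0, {"N2": 300}, spk_z={"C3": 6.0},
            power_1hz_z={"C3": -4.5}, power_25hz_z={"C3": 4.5})
        assert set(rep.reasons) == {"spk_gt_5sd", "power_outlier_1hz",
                                    "power_outlier_25hz"}

    def test_ambiguous_polarity_excluded(self):
        rep = apply_record_exclusions(400.0, {"N2": 300},
                                      polarity={"decision": "ambiguous"})
        assert rep.reasons == ["polarity_ambiguous"]
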