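"""Synthetic LFP generator: determinism, calibration, closed-form gains."""

from dataclasses import replace

import numpy as np
import pytest

from optolfp.io_core import PulseSchedule, SessionLayout, ValidationError
from optolfp.preprocess import MaskedSignal, build_mask, downsample
from optolfp.linelength import line_length
from optolfp.spectral import band_auc, welch_psd
from optolfp.synthetic_lfp import (BurstModel, GSModel, OscillatorSpec,
                                   PulseResponseSpec, SimulationConfig,
                                   default_config, generate_background,
                                   insert_bursts, insert_generalized_seizure,
                                   pulse_gain_trace, simulate_experiment)


@pytest.fixture(scope="module")
def tiny():
    return SessionLayout(hour_s=120.0, fadeoff_s=20.0)


class TestBackground:
    def test_zero_amplitudes_give_zero_trace(self, tiny):
        cfg = SimulationConfig(fs_raw=500.0, layout=tiny, background_rms=0.0,
                               oscillators=(), habituation=(1, 1, 1))
        assert np.all(generate_background(cfg, 0) == 0)

    def test_same_seed_identical_traces(self, tiny):
        cfg = SimulationConfig(fs_raw=500.0, layout=tiny)
        a = generate_background(cfg, 5)
        b = generate_background(cfg, 5)
        np.testing.assert_array_equal(a, b)
        c = generate_background(cfg, 6)
        assert not np.array_equal(a, c)

    def test_channels_are_independent_draws(self, tiny):
        cfg = SimulationConfig(fs_raw=500.0, layout=tiny)
        assert not np.array_equal(generate_background(cfg, 5, 0),
                                  generate_background(cfg, 5, 1))

    def test_theta_band_auc_matches_configured_rms(self, tiny):
        """theta-only trace: band AUC ~ RMS^2 (0.15^2 = 0.0225 mV^2)."""
        cfg = SimulationConfig(
            fs_raw=1000.0, layout=tiny, background_rms=0.0,
            oscillators=(OscillatorSpec(7.0, 3.0, 0.15),))
        x = generate_background(cfg, 3)
        psd = welch_psd(x, 1000.0)
        assert band_auc(psd, (4.0, 12.0)) == pytest.approx(0.0225, rel=0.10)


class TestPulseGain:
    def test_zero_depth_gain_is_unity(self):
        sch = PulseSchedule(frequency=0.1, light_on=(0.0, 100.0),
                            fadeoff_tail=0.0)
        g = pulse_gain_trace(sch, "suppress", 0.0, 3.0, 100.0, 500.0)
        assert np.all(g == 1.0)

    def test_single_pulse_mean_gain_closed_form(self):
        """suppress s=0.4, tau=3: mean g over (0, 2] = 1 - 0.4*(3/2)(1-e^-2/3)."""
        sch = PulseSchedule(frequency=0.01, light_on=(0.0, 99.0),
                            fadeoff_tail=0.0)
        g = pulse_gain_trace(sch, "suppress", 0.4, 3.0, 99.0, 1000.0)
        expected = 1 - 0.4 * (3.0 / 2.0) * (1 - np.exp(-2.0 / 3.0))
        assert g[1:2001].mean() == pytest.approx(expected, rel=1e-3)

    def test_steady_state_superposition_closed_form(self):
        """suppress s=0.25, tau=12 at 0.1 Hz: g(p_k + 1) -> geometric sum."""
        sch = PulseSchedule(frequency=0.1, light_on=(0.0, 2000.0),
                            fadeoff_tail=0.0)
        g = pulse_gain_trace(sch, "suppress", 0.25, 12.0, 2000.0, 1000.0)
        expected = 1 - 0.25 * np.exp(-1 / 12.0) / (1 - np.exp(-10 / 12.0))
        assert g[1_991_000] == pytest.approx(expected, rel=1e-3)

    def test_gain_unity_outside_light_window_and_floored(self):
        sch = PulseSchedule(frequency=0.1, light_on=(50.0, 150.0),
                            fadeoff_tail=0.0)
        g = pulse_gain_trace(sch, "suppress", 0.9, 50.0, 200.0, 100.0)
        assert np.all(g[:5000] == 1.0) and np.all(g[15000:] == 1.0)
        assert g.min() >= 0.05

    def test_enhance_mirrors_suppress(self):
        sch = PulseSchedule(frequency=0.1, light_on=(0.0, 100.0),
                            fadeoff_tail=0.0)
        gs = pulse_gain_trace(sch, "suppress", 0.3, 5.0, 100.0, 500.0)
        ge = pulse_gain_trace(sch, "enhance", 0.3, 5.0, 100.0, 500.0)
        np.testing.assert_allclose(ge - 1.0, 1.0 - gs, atol=1e-12)


class TestBursts:
    def test_zero_rate_leaves_signal_unchanged(self, rng):
        x = rng.normal(0, 0.2, 100_000)
        model = BurstModel(burst_rate_per_h=0.0)
        y, spikes, bursts = insert_bursts(x, 500.0, model, seed=1)
        np.testing.assert_array_equal(x, y)
        assert spikes.size == 0 and bursts == []

    def test_truth_time_fraction_arithmetic(self, rng):
        """3 bursts of 60 s in 1800 s -> truth fraction 0.1."""
        x = rng.normal(0, 0.2, int(1800 * 500))
        model = BurstModel(burst_rate_per_h=6.0, burst_duration=(60.0, 60.0))
        _, _, bursts = insert_bursts(x, 500.0, model, seed=2)
        assert len(bursts) == 3
        total = sum(b - a for a, b, _ in bursts)
        assert total / 1800.0 == pytest.approx(0.1, abs=1e-9)

    def test_same_seed_identical_spike_times(self, rng):
        x = rng.normal(0, 0.2, int(600 * 500))
        model = BurstModel(burst_rate_per_h=12.0)
        _, s1, _ = insert_bursts(x, 500.0, model, seed=3)
        _, s2, _ = insert_bursts(x, 500.0, model, seed=3)
        np.testing.assert_array_equal(s1, s2)

    def test_overlapping_spike_kernel_rejected(self):
        with pytest.raises(ValidationError):
            BurstModel(spike_rate=30.0, kernel_width=0.040)


class TestGeneralizedSeizure:
    def test_postictal_rms_matches_gain(self, rng):
        fs = 500.0
        data = rng.normal(0, 0.2, (2, int(400 * fs)))
        pre_rms = np.sqrt(np.mean(data[:, :int(100 * fs)] ** 2, axis=1))
        out, iv = insert_generalized_seizure(data, fs, 100.0, 30.0,
                                             postictal_gain=0.2,
                                             postictal_duration=60.0)
        post = out[:, int(130 * fs):int(190 * fs)]
        post_rms = np.sqrt(np.mean(post ** 2, axis=1))
        np.testing.assert_allclose(post_rms, 0.2 * pre_rms, rtol=0.15)
        assert iv == (100.0, 130.0)

    def test_discharge_hits_both_channels(self, rng):
        fs = 500.0
        data = rng.normal(0, 0.2, (2, int(300 * fs)))
        out, _ = insert_generalized_seizure(data, fs, 50.0, 30.0)
        seg = slice(int(55 * fs), int(75 * fs))
        for c in range(2):
            assert np.max(np.abs(out[c, seg])) > 4 * 0.2

    def test_zero_duration_changes_nothing(self, rng):
        data = rng.normal(size=(2, 5000))
        out, _ = insert_generalized_seizure(data, 500.0, 1.0, 0.0)
        np.testing.assert_array_equal(out, data)

    def test_truncation_warns(self, rng):
        data = rng.normal(size=(2, int(100 * 500)))
        with pytest.warns(UserWarning):
            insert_generalized_seizure(data, 500.0, 90.0, 30.0)


class TestSimulateExperiment:
    def test_ref_session_with_pulse_response_rejected(self, tiny):
        with pytest.raises(ValidationError):
            SimulationConfig(layout=tiny, session="ref",
                             pulse_response=PulseResponseSpec("suppress"))

    def test_deterministic_and_byte_identical_edf(self, tiny, tmp_path):
        from optolfp.io_core import write_recording
        cfg = default_config("PACK", "saline", "ref", layout=tiny,
                             fs_raw=500.0, seed=9)
        r1, t1 = simulate_experiment(cfg)
        r2, t2 = simulate_experiment(cfg)
        np.testing.assert_array_equal(r1.data, r2.data)
        write_recording(r1, tmp_path / "a.edf", tmp_path / "a.csv")
        write_recording(r2, tmp_path / "b.edf", tmp_path / "b.csv")
        assert (tmp_path / "a.edf").read_bytes() == (tmp_path / "b.edf").read_bytes()

    def test_gs_annotated_and_bilateral(self, tiny):
        cfg = default_config("bPAC", "saline", "ref", layout=tiny,
                             fs_raw=500.0, seed=2)
        cfg = replace(cfg, gs_model=GSModel(rate_per_session=2.0,
                                            duration=10.0,
                                            postictal_duration=10.0))
        rec, truth = simulate_experiment(cfg)
        assert len(truth.gs_intervals) >= 1
        iv = rec.annotations.intervals("GS")
        assert len(iv) == len(truth.gs_intervals)
        # exclusion interval covers discharge plus postictal depression
        assert iv[0][1] - iv[0][0] >= 10.0 + 10.0 - 1e-9

    def test_propagation_copies_bursts_contralaterally(self, tiny):
        cfg = default_config("no_virus", "kainate", "ref", layout=tiny,
                             fs_raw=500.0, seed=4)
        cfg = replace(cfg, burst_model=BurstModel(
            burst_rate_per_h=30.0, burst_duration=(15.0, 15.0),
            propagate=True))
        rec, truth = simulate_experiment(cfg)
        assert len(truth.bursts["HCi"]) > 0
        assert len(truth.bursts["HCc"]) == len(truth.bursts["HCi"])

    def test_no_propagation_keeps_contralateral_clean(self, tiny):
        cfg = default_config("PACK", "kainate", "ref", layout=tiny,
                             fs_raw=500.0, seed=4)
        cfg = replace(cfg, burst_model=BurstModel(
            burst_rate_per_h=30.0, burst_duration=(15.0, 15.0)))
        rec, truth = simulate_experiment(cfg)
        assert truth.bursts["HCc"] == []
        assert truth.spike_times["HCc"].size == 0

    def test_gain_positivity(self, tiny):
        cfg = default_config("PACK", "saline", "stim_0.1", layout=tiny,
                             fs_raw=500.0, seed=1)
        _, truth = simulate_experiment(cfg)
        for g in truth.gain.values():
            assert np.all(g >= 0.05)


class TestLinearityHook:
    def test_line_length_scales_with_mean_gain(self, rng):
        """L(gain x stationary trace) ~ mean(gain) x L(trace) per 2-s window."""
        fs = 500.0
        x = rng.normal(0, 0.2, int(20 * fs))
        t = np.arange(x.size) / fs
        gain = 1.0 - 0.4 * np.exp(-t / 3.0)
        for w0 in (0.0, 4.0, 10.0):
            sel = slice(int(w0 * fs), int((w0 + 2) * fs))
            L_mod = line_length(MaskedSignal((gain * x)[sel], fs))
            L_ref = line_length(MaskedSignal(x[sel], fs))
            assert L_mod == pytest.approx(gain[sel].mean() * L_ref, rel=0.03)
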