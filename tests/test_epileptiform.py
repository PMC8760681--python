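"""Spike detection, burst grouping, load classes, burst ratio."""

import numpy as np
import pytest

from optolfp.epileptiform import (Burst, SpikeEvent, burst_ratio,
                                  classify_load, classify_spike_load,
                                  detect_spikes, group_bursts)
from optolfp.io_core import EventList, SessionLayout, ValidationError
from optolfp.preprocess import MaskedSignal
from optolfp.synthetic_lfp import (SimulationConfig, _spike_kernel,
                                   generate_background, robust_sd)

FS = 500.0


@pytest.fixture(scope="module")
def background():
    """600 s of realistic synthetic background at 500 Hz."""
    lay = SessionLayout(hour_s=200.0, fadeoff_s=20.0)
    cfg = SimulationConfig(fs_raw=FS, layout=lay)
    return generate_background(cfg, seed=11)


class TestDetectSpikes:
    def test_false_positive_rate_on_pure_background(self, background):
        spikes = detect_spikes(MaskedSignal(background, FS))
        assert len(spikes) / (background.size / FS) < 0.05

    def test_recovers_inserted_sharp_waves(self, background):
        x = background.copy()
        kernel = 8.0 * robust_sd(x) * _spike_kernel(0.040, FS)
        peak = int(np.argmax(np.abs(kernel)))
        truth = np.arange(3.0, 3.0 + 100 * 0.5, 0.5)  # 100 spikes, 2 Hz
        for t in truth:
            i = int(round(t * FS)) - peak
            x[i:i + kernel.size] += kernel
        det = np.array([s.time for s in detect_spikes(MaskedSignal(x, FS))])
        hits = sum(np.min(np.abs(det - t)) <= 0.010 for t in truth)
        assert hits >= 95

    def test_all_masked_signal_yields_no_events(self, background):
        sig = MaskedSignal(background, FS,
                           np.ones(background.size, dtype=bool))
        assert detect_spikes(sig) == []

    def test_flat_signal_is_an_error(self):
        with pytest.raises(ValidationError):
            detect_spikes(MaskedSignal(np.zeros(int(60 * FS)), FS))

    def test_deterministic(self, background):
        a = detect_spikes(MaskedSignal(background, FS))
        b = detect_spikes(MaskedSignal(background, FS))
        assert a == b


def _events(times):
    return [SpikeEvent(time=float(t)) for t in times]


class TestGroupBursts:
    def test_five_consecutive_spikes_form_one_burst(self):
        bursts = group_bursts(_events([0, 1, 2, 3, 4]))
        assert len(bursts) == 1 and bursts[0].n_spikes == 5

    def test_short_runs_are_discarded(self):
        assert group_bursts(_events([0, 1, 2, 10, 11, 12])) == []

    def test_long_run_span_with_padding(self):
        bursts = group_bursts(_events(np.arange(20.0)), pad=0.020)
        assert len(bursts) == 1
        assert bursts[0].duration == pytest.approx(19.0 + 0.040)


class TestClassifyLoad:
    @pytest.mark.parametrize("n,dur,expected", [
        (30, 20.0, "high"),    # 1.5 Hz, >= 10 s
        (6, 15.0, "low"),      # 0.4 Hz
        (12, 20.0, "medium"),  # 0.6 Hz
        (15, 5.0, "medium"),   # 3 Hz but too short for high
    ])
    def test_threshold_arithmetic(self, n, dur, expected):
        assert classify_spike_load(n, dur) == expected

    def test_zero_duration_rejected(self):
        with pytest.raises(ValidationError):
            classify_spike_load(5, 0.0)

    def test_every_burst_gets_exactly_one_class(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            dur = float(rng.uniform(0.5, 40.0))
            assert classify_spike_load(n, dur) in ("low", "medium", "high")


def _burst(onset, dur, n):
    b = Burst(onset=onset, offset=onset + dur,
              spike_times=np.linspace(onset, onset + dur, n))
    b.load_class = classify_load(b)
    return b


class TestBurstRatio:
    def test_no_bursts_is_zero(self):
        assert burst_ratio([], 1800.0).ratio == 0.0

    def test_three_highload_bursts_fraction(self):
        bursts = [_burst(100.0 + 500 * i, 60.0, 90) for i in range(3)]
        assert burst_ratio(bursts, 1800.0).ratio == pytest.approx(0.1)

    def test_gs_session_reported_missing_not_zero(self):
        ann = EventList.from_records([("GS", 50.0, 30.0)])
        summ = burst_ratio([], 1800.0, gs_annotations=ann)
        assert summ.dropped_gs and summ.ratio is None

    def test_raising_high_rate_threshold_never_raises_ratio(self):
        bursts = [_burst(0.0, 30.0, 40), _burst(100.0, 20.0, 12)]
        def ratio_at(thr):
            tot = 0.0
            for b in bursts:
                if classify_load(b, {"high_rate": thr}) == "high":
                    tot += b.duration
            return tot / 1800.0
        ratios = [ratio_at(thr) for thr in (0.5, 1.0, 1.5, 2.0)]
        assert all(a >= b for a, b in zip(ratios, ratios[1:]))


class TestGeneralizedSeizureDetector:
    def test_finds_inserted_bilateral_discharge(self):
        from optolfp.epileptiform import detect_generalized_seizures
        from optolfp.synthetic_lfp import (SimulationConfig,
                                           generate_background,
                                           insert_generalized_seizure)
        lay = SessionLayout(hour_s=200.0, fadeoff_s=20.0)
        cfg = SimulationConfig(fs_raw=FS, layout=lay)
        data = np.vstack([generate_background(cfg, 3, 0),
                          generate_background(cfg, 3, 1)])
        assert len(detect_generalized_seizures(data, FS)) == 0
        out, _ = insert_generalized_seizure(data, FS, 200.0, 30.0, 0.2, 60.0)
        ev = detect_generalized_seizures(out, FS)
        assert len(ev) == 1
        onset = ev.table["onset_s"].iloc[0]
        offset = onset + ev.table["duration_s"].iloc[0]
        assert onset == pytest.approx(200.0, abs=2.0)
        assert offset == pytest.approx(230.0, abs=2.0)

    def test_unilateral_activity_not_flagged(self, background):
        from optolfp.epileptiform import detect_generalized_seizures
        from optolfp.synthetic_lfp import insert_generalized_seizure
        data = np.vstack([background, background[::-1]])
        loud, _ = insert_generalized_seizure(data[:1], FS, 200.0, 30.0,
                                             0.2, 60.0)
        both = np.vstack([loud[0], data[1]])
        assert len(detect_generalized_seizures(both, FS)) == 0
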