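"""SD and PIP detectors: rule transcription, metric recovery, bookkeeping."""

import numpy as np
import pytest

import neurovasc as nv
from neurovasc.events import SdEvent, detect_pips, detect_sds, sd_auc
from neurovasc.lfp import LfpTrace
from neurovasc.synthetic import PipSpec, SdSpec

FS = 1000.0


def _baseline_trace(duration=300.0, mean=4.0, sd=0.1, fs=FS):
    """Baseline whose SD is set by a deterministic sinusoid (noise-free
    elsewhere), so rule-boundary cases can be constructed exactly."""
    n = int(duration * fs)
    x = np.full(n, mean)
    t = np.arange(int(60 * fs)) / fs
    x[: t.size] += sd * np.sqrt(2) * np.sin(2 * np.pi * 3 * t)
    return x


def _with_rectangle(depth_in_sds, dur, fs=FS):
    x = _baseline_trace(fs=fs)
    sd_emp = float(np.std(x[: int(60 * fs)]))
    i0, i1 = int(120 * fs), int((120 + dur) * fs)
    x[i0:i1] -= depth_in_sds * sd_emp
    return LfpTrace(x, fs=fs)


class TestSdDetector:
    def test_flat_trace_yields_nothing(self):
        rng = np.random.default_rng(0)
        tr = LfpTrace(4.0 + 0.05 * rng.standard_normal(int(300 * FS)), fs=FS)
        assert detect_sds(tr, (0, 60)) == []

    def test_nine_sd_deflection_is_subthreshold(self):
        # 9 x baseline SD for 60 s: below the printed 10-SD rule
        assert detect_sds(_with_rectangle(9.0, 60), (0, 60)) == []

    @pytest.mark.parametrize(
        "depth,dur,expected",
        [(9.9, 60, 0), (10.1, 11, 1), (10.1, 9, 0)],
        ids=["9.9sd-never", "10.1sd-11s-always", "10.1sd-9s-never"],
    )
    def test_rule_boundary_exactness(self, depth, dur, expected):
        assert len(detect_sds(_with_rectangle(depth, dur), (0, 60))) == expected

    def test_synthetic_sd_metrics_recovered(self):
        trace, _ = nv.generate_lfp(
            300, fs=FS, baseline_sd=0.1,
            sd_specs=[SdSpec(onset=120, amplitude=20, duration=60)], seed=1,
        )
        events = detect_sds(trace, (0, 60))
        assert len(events) == 1
        e = events[0]
        # amplitude reads the raw-trace minimum, which overshoots the true
        # depth by the expected extremum of ~60k noise samples (~4.5 sigma)
        assert e.amplitude == pytest.approx(20.0, abs=0.6)
        assert e.duration == pytest.approx(60.0, abs=2.0)

    def test_truncated_event_flagged(self):
        x = _baseline_trace()
        x[int(120 * FS):] -= 20.0  # never recovers
        events = detect_sds(LfpTrace(x, fs=FS), (0, 60))
        assert len(events) == 1
        assert events[0].truncated
        assert events[0].end == pytest.approx(300.0, abs=0.1)

    def test_staircase_rebaselining(self):
        # second SD sits on a shifted post-event baseline; adaptive
        # re-baselining must still catch it
        rng = np.random.default_rng(3)
        n = int(700 * FS)
        x = 4.0 + 0.05 * rng.standard_normal(n)
        t = np.arange(n) / FS
        x[(t >= 100) & (t < 160)] -= 15.0
        x[t >= 160] -= 0.5  # shifted post-event baseline, within 80% recovery
        x[(t >= 400) & (t < 460)] -= 15.0
        events = detect_sds(LfpTrace(x, fs=FS), (0, 60))
        assert len(events) == 2
        assert events[1].onset == pytest.approx(400.0, abs=1.0)
        assert events[1].amplitude == pytest.approx(15.0, abs=0.5)

    def test_zero_baseline_sd_rejected(self):
        tr = LfpTrace(np.full(int(100 * FS), 4.0), fs=FS)
        with pytest.raises(ValueError, match="zero"):
            detect_sds(tr, (0, 60))

    def test_delay_from_injection(self):
        trace, _ = nv.generate_lfp(
            300, fs=FS, sd_specs=[SdSpec(onset=180, amplitude=20, duration=60)],
            seed=2,
        )
        e = detect_sds(trace, (0, 60), injection_time=120.0)[0]
        assert e.delay_from_injection == pytest.approx(1.0, abs=0.05)


class TestSdAuc:
    def test_rectangle(self):
        x = np.full(int(400 * FS), 4.0)
        x[int(60 * FS):int(180 * FS)] -= 12.0  # 12 mV for 2 min
        e = SdEvent(onset=60, end=180, amplitude=12, duration=120, auc=0)
        auc = sd_auc(e, LfpTrace(x, fs=FS), 4.0)
        assert auc == pytest.approx(24.0, rel=0.01)

    def test_degenerate_zero_duration(self):
        x = np.full(int(10 * FS), 4.0)
        e = SdEvent.__new__(SdEvent)  # bypass end>onset validation
        e.onset, e.end = 5.0, 5.0
        assert sd_auc(e, LfpTrace(x, fs=FS), 4.0) == 0.0

    def test_trapezoid_closed_form(self):
        # 10 mV deep, 100 s plateau, 20 s linear ramps: trapezoid area
        # = 10 * (100 + 140) / 2 = 1200 s*mV = 20 mV*min
        fs = FS
        x = np.full(int(400 * fs), 4.0)
        t = np.arange(x.size) / fs
        depth = np.interp(t, [100, 120, 220, 240], [0, 10, 10, 0])
        x -= depth
        e = SdEvent(onset=100, end=240, amplitude=10, duration=140, auc=0)
        assert sd_auc(e, LfpTrace(x, fs=fs), 4.0) == pytest.approx(1200 / 60, rel=0.01)


class TestPipDetector:
    def test_three_second_burst_detected(self):
        trace, _ = nv.generate_lfp(
            120, fs=FS, pip_specs=[PipSpec(onset=80, duration=3.0, f_center=6.0)],
            seed=4,
        )
        events = detect_pips(trace, (0, 60))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(3.0, abs=0.5)
        assert "theta" in events[0].bands
        assert events[0].peak_z > 2

    def test_one_second_burst_rejected(self):
        trace, _ = nv.generate_lfp(
            120, fs=FS, pip_specs=[PipSpec(onset=80, duration=1.0, f_center=6.0)],
            seed=5,
        )
        assert detect_pips(trace, (0, 60)) == []

    def test_dc_offset_invariance(self):
        trace, _ = nv.generate_lfp(
            120, fs=FS, pip_specs=[PipSpec(onset=80, duration=3.0)], seed=6,
        )
        shifted = LfpTrace(trace.samples + 50.0, fs=trace.fs)
        a = detect_pips(trace, (0, 60))
        b = detect_pips(shifted, (0, 60))
        assert len(a) == len(b) == 1
        assert a[0].onset == pytest.approx(b[0].onset, abs=1e-6)

    def test_alpha_burst_tagged_alpha(self):
        trace, _ = nv.generate_lfp(
            120, fs=FS, pip_specs=[PipSpec(onset=80, duration=3.0, f_center=12.0)],
            seed=7,
        )
        events = detect_pips(trace, (0, 60))
        assert len(events) == 1
        assert "alpha" in events[0].bands

    def test_both_bands_policy_stricter(self):
        # a pure 6 Hz burst drives theta strongly; requiring simultaneous
        # theta AND alpha supra-threshold runs can only shrink the result
        trace, _ = nv.generate_lfp(
            120, fs=FS, pip_specs=[PipSpec(onset=80, duration=3.0, f_center=6.0)],
            seed=8,
        )
        either = detect_pips(trace, (0, 60), combine="either_band")
        both = detect_pips(trace, (0, 60), combine="both_bands")
        dur_e = sum(e.duration for e in either)
        dur_b = sum(e.duration for e in both)
        assert dur_b <= dur_e + 1e-9

    def test_short_baseline_rejected(self):
        trace, _ = nv.generate_lfp(60, fs=FS, seed=9)
        with pytest.raises(ValueError, match="10 s"):
            detect_pips(trace, (0, 5))


class TestLocations:
    def test_counting(self):
        def mk(n):
            return [SdEvent(onset=i, end=i + 1, amplitude=5, duration=1, auc=0)
                    for i in range(n)]
        counts = nv.classify_event_locations(
            {"injection_site": mk(3), "peri_injection": mk(5)}
        )
        assert counts == {"injection_site": 3, "peri_injection": 5}

    def test_empty(self):
        assert nv.classify_event_locations({}) == {"injection_site": 0,
                                                   "peri_injection": 0}

    def test_untagged_channel_warns_and_excludes(self):
        evs = [SdEvent(onset=0, end=1, amplitude=5, duration=1, auc=0)]
        with pytest.warns(UserWarning, match="unknown"):
            counts = nv.classify_event_locations({"channel_7": evs})
        assert counts == {"injection_site": 0, "peri_injection": 0}
        assert evs[0].location == "unknown"

    def test_scenario_counts_match_ground_truth(self, compact_config):
        _, lfp, truth = nv.generate_scenario(compact_config, lfp_fs=500,
                                             render_kymograph=False)
        sds = detect_sds(lfp, (0, compact_config.injection_time))
        counts = nv.classify_event_locations({"injection_site": sds})
        assert counts["injection_site"] == len(truth.sd_events)
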