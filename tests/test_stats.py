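"""Chi-squared uniformity test, Pearson correlation, and the report builder."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import neurovasc as nv
from neurovasc.events import PipEvent, SdEvent
from neurovasc.lspiv import VelocityTrace
from neurovasc.segmentation import segment_periods


class TestChiSquaredUniform:
    def test_perfect_uniformity(self):
        r = nv.chi_squared_uniform([10, 10])
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert r.df == 1

    def test_location_counts_closed_form(self):
        # counts (39, 18): e = 28.5, statistic = 2 * 10.5^2 / 28.5
        r = nv.chi_squared_uniform([39, 18])
        assert r.statistic == pytest.approx(7.7368, abs=1e-4)
        assert r.df == 1

    def test_five_zero_closed_form(self):
        assert nv.chi_squared_uniform([5, 0]).statistic == pytest.approx(5.0)

    def test_exact_p_matches_brute_enumeration(self):
        # independent oracle: enumerate all 2^n assignments of n events
        for n in range(1, 13):
            e = n / 2
            stats = []
            for bits in itertools.product((0, 1), repeat=n):
                c = sum(bits)
                stats.append(((c - e) ** 2 + (n - c - e) ** 2) / e)
            for c0 in range(n + 1):
                s_obs = ((c0 - e) ** 2 + (n - c0 - e) ** 2) / e
                brute = sum(1 for s in stats if s >= s_obs - 1e-12) / 2**n
                exact = nv.chi_squared_uniform([c0, n - c0], method="exact")
                assert exact.p_value == pytest.approx(brute, abs=1e-12)

    def test_exact_p_three_cells(self):
        # all 3^5 assignments of 5 events to 3 cells
        e = 5 / 3
        stats = []
        for assign in itertools.product((0, 1, 2), repeat=5):
            cells = [assign.count(k) for k in range(3)]
            stats.append(sum((o - e) ** 2 / e for o in cells))
        obs = [3, 1, 1]
        s_obs = sum((o - e) ** 2 / e for o in obs)
        brute = sum(1 for s in stats if s >= s_obs - 1e-12) / 3**5
        r = nv.chi_squared_uniform(obs, method="exact")
        assert r.df == 2
        assert r.p_value == pytest.approx(brute, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            nv.chi_squared_uniform([0, 0])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(counts=st.lists(st.integers(min_value=0, max_value=50),
                           min_size=2, max_size=5).filter(lambda c: sum(c) > 0))
    def test_statistic_permutation_invariant_and_nonnegative(self, counts):
        r1 = nv.chi_squared_uniform(counts)
        r2 = nv.chi_squared_uniform(list(reversed(counts)))
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.statistic >= 0.0


class TestPearson:
    def test_perfect_correlations(self):
        assert nv.pearson_correlation([1, 2, 3], [1, 2, 3]).statistic == \
            pytest.approx(1.0)
        assert nv.pearson_correlation([1, 2, 3], [-1, -2, -3]).statistic == \
            pytest.approx(-1.0)

    def test_four_point_hand_oracle(self):
        # sums: Sxy = 11.5, Sxx = 5, Syy = 26.75 -> r = 11.5/sqrt(133.75)
        r = nv.pearson_correlation([1, 2, 3, 4], [2, 4, 6, 9])
        assert r.statistic == pytest.approx(11.5 / np.sqrt(5 * 26.75), abs=1e-6)
        assert r.df == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            nv.pearson_correlation([1, 1, 1], [1, 2, 3])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=10_000),
           a=st.floats(min_value=0.1, max_value=50.0),
           b=st.floats(min_value=-100.0, max_value=100.0))
    def test_affine_invariance(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        r0 = nv.pearson_correlation(x, y)
        r1 = nv.pearson_correlation(a * x + b, y)
        assert r1.statistic == pytest.approx(r0.statistic, abs=1e-9)
        r2 = nv.pearson_correlation(-a * x + b, y)
        assert r2.statistic == pytest.approx(-r0.statistic, abs=1e-9)


def _tiny_experiment():
    t = np.arange(0.0, 900.0, 0.5)
    v = np.interp(t, [0, 120, 180, 500, 560, 900], [6, 6, 1.8, 2.0, 5.2, 5.2])
    trace = VelocityTrace(t, v, np.ones_like(t))
    seg = segment_periods(trace, 120.0)
    sds = [
        SdEvent(onset=200, end=260, amplitude=20, duration=60, auc=20,
                location="injection_site"),
        SdEvent(onset=320, end=380, amplitude=15, duration=60, auc=15,
                location="peri_injection"),
    ]
    pips = [PipEvent(onset=600 + 30 * i, duration=2.5, bands=("theta",), peak_z=5)
            for i in range(3)]
    return trace, seg, sds, pips


class TestBuildReport:
    def test_null_scenario_tests_marked_na(self):
        trace, seg, _, _ = _tiny_experiment()
        doc = nv.build_report(trace, seg, [], [])
        assert doc["sd_events"] == []
        assert "not applicable" in doc["sd_location_uniformity"]
        assert "not applicable" in doc["sd_auc_vs_pip_count"]

    def test_counts_and_tests_present(self):
        trace, seg, sds, pips = _tiny_experiment()
        doc = nv.build_report(trace, seg, sds, pips,
                              experiment_points=[(10, 2), (20, 5), (30, 7), (5, 1)])
        assert len(doc["sd_events"]) == 2
        assert len(doc["pip_events"]) == 3
        assert doc["sd_location_counts"] == {"injection_site": 1,
                                             "peri_injection": 1}
        assert doc["sd_location_uniformity"]["statistic"] == 0.0
        assert doc["sd_auc_vs_pip_count"]["statistic"] > 0.9

    def test_deterministic_regeneration(self):
        trace, seg, sds, pips = _tiny_experiment()
        a = nv.build_report(trace, seg, sds, pips)
        b = nv.build_report(trace, seg, sds, pips)
        assert a == b

    def test_mismatched_time_bases_rejected(self):
        trace, seg, sds, pips = _tiny_experiment()
        bad = [SdEvent(onset=5000, end=5060, amplitude=20, duration=60, auc=20)]
        with pytest.raises(ValueError, match="time bases"):
            nv.build_report(trace, seg, bad, [])

    def test_json_serializable(self, tmp_path):
        import json
        trace, seg, sds, pips = _tiny_experiment()
        doc = nv.build_report(trace, seg, sds, pips)
        nv.write_report(tmp_path / "r.json", doc)
        back = json.loads((tmp_path / "r.json").read_text())
        assert back["schema_version"] == doc["schema_version"]


def test_auc_pip_correlation_recovered_from_detections():
    """Experiments whose PIP count scales with total SD AUC must yield a
    strongly positive detected-AUC vs detected-count correlation."""
    import neurovasc as nv
    wins = 0
    n_runs = 10
    for run in range(n_runs):
        points = []
        for k in range(6):
            dur = 20.0 + 10.0 * ((k + run) % 5)
            amp = 12.0 + 3.0 * (k % 4)
            n_pips = max(1, int(round(amp * dur / 60.0 / 3.0)))
            sd_specs = [nv.SdSpec(onset=90.0, amplitude=amp, duration=dur)]
            pip_specs = [
                nv.PipSpec(onset=90.0 + dur + 20.0 + 8.0 * i, duration=2.5)
                for i in range(n_pips)
            ]
            total = pip_specs[-1].end + 15.0
            trace, _ = nv.generate_lfp(total, fs=500, sd_specs=sd_specs,
                                       pip_specs=pip_specs, seed=1000 * run + k)
            sds = nv.detect_sds(trace, (0, 60))
            pips = nv.detect_pips(trace, (0, 60))
            points.append((sum(e.auc for e in sds), len(pips)))
        r = nv.pearson_correlation([p[0] for p in points],
                                   [p[1] for p in points])
        wins += r.statistic > 0.5
    assert wins >= 0.9 * n_runs
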