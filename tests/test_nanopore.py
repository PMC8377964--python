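"""Nanopore event detection, ECD integration and MW calibration."""

import numpy as np
import pytest

from hyalkit.nanopore import (
    CurrentTrace,
    NanoporeEvent,
    detect_events,
    ecd_to_mw,
    estimate_baseline_sigma,
    event_ecd,
    events_to_mw_summary,
    fit_ecd_calibration,
    lowpass_filter,
)
from hyalkit.simulate import gen_mw_lognormal, gen_nanopore_trace

FS = 200_000.0


def _trace_with_pulse(n=20000, baseline=1000.0, depth=0.0, start=5000, length=20):
    cur = np.full(n, baseline)
    cur[start : start + length] -= depth
    return CurrentTrace(cur, FS)


class TestLowpass:
    def test_dc_preserved(self):
        t = CurrentTrace(np.full(5000, 123.4), FS)
        out = lowpass_filter(t)
        np.testing.assert_allclose(out.current_pa, 123.4, rtol=1e-9)

    @pytest.mark.parametrize(
        "freq, check",
        [(50_000.0, lambda r: r < 0.1), (100.0, lambda r: abs(r - 1) < 0.01)],
    )
    def test_frequency_response(self, freq, check):
        """Stopband tone attenuated >= 20 dB; passband tone within 1%."""
        t = np.arange(100_000) / FS
        sine = np.sin(2 * np.pi * freq * t)
        out = lowpass_filter(CurrentTrace(sine, FS)).current_pa
        core = slice(10_000, 90_000)  # ignore filter edge transients
        ratio = out[core].std() / sine[core].std()
        assert check(ratio)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            lowpass_filter(CurrentTrace(np.zeros(100), FS), cutoff_hz=150_000)


class TestBaselineSigma:
    def test_constant_trace(self):
        b, s = estimate_baseline_sigma(CurrentTrace(np.full(2000, 42.0), FS))
        assert b == 42.0 and s == 0.0

    def test_gaussian_noise_sigma_within_5pct(self):
        rng = np.random.default_rng(123)
        t = CurrentTrace(rng.normal(100.0, 2.0, size=1_000_000), FS)
        b, s = estimate_baseline_sigma(t)
        assert b == pytest.approx(100.0, abs=0.05)
        assert s == pytest.approx(2.0, rel=0.05)

    def test_robust_to_events(self):
        """1% of samples replaced by deep blockades shifts baseline/sigma < 2%."""
        rng = np.random.default_rng(7)
        x = rng.normal(100.0, 2.0, size=500_000)
        b0, s0 = estimate_baseline_sigma(CurrentTrace(x, FS))
        x2 = x.copy()
        idx = rng.choice(len(x), size=len(x) // 100, replace=False)
        x2[idx] -= 50.0
        b1, s1 = estimate_baseline_sigma(CurrentTrace(x2, FS))
        assert abs(b1 - b0) / abs(b0) < 0.02
        assert abs(s1 - s0) / s0 < 0.02

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            estimate_baseline_sigma(CurrentTrace(np.zeros(10), FS))


class TestDetect:
    def test_single_rectangular_pulse(self):
        # depth 10 sigma, duration 100 us = 20 samples
        t = _trace_with_pulse(depth=10.0, length=20)
        events = detect_events(t, 1000.0, 1.0)
        assert len(events) == 1
        assert events[0].start_idx == 5000 and events[0].end_idx == 5020
        assert events[0].duration_s == pytest.approx(100e-6)

    def test_subthreshold_pulse_ignored(self):
        t = _trace_with_pulse(depth=3.0, length=20)
        assert detect_events(t, 1000.0, 1.0) == []

    @pytest.mark.parametrize("length", [2, 1000])  # 10 us and 5 ms
    def test_duration_gate(self, length):
        t = _trace_with_pulse(depth=10.0, length=length)
        assert detect_events(t, 1000.0, 1.0) == []

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        cur = rng.normal(500.0, 1.0, 50_000)
        cur[10_000:10_030] -= 20.0
        t1 = CurrentTrace(cur, FS)
        t2 = CurrentTrace(cur + 777.0, FS)
        e1 = detect_events(t1, 500.0, 1.0)
        e2 = detect_events(t2, 1277.0, 1.0)
        assert [(e.start_idx, e.end_idx) for e in e1] == [
            (e.start_idx, e.end_idx) for e in e2
        ]
        assert [e.ecd_pas for e in e1] == pytest.approx([e.ecd_pas for e in e2])

    def test_noiseless_synthetic_exact_recovery(self, ecd_calibration):
        dist, _ = gen_mw_lognormal(1000.0, 1.5)
        trace, truth = gen_nanopore_trace(
            dist, ecd_calibration, event_rate_hz=30, sigma_pa=0.0, duration_s=2.0, seed=3
        )
        events = detect_events(trace, 4000.0, 1.0)
        assert len(events) == len(truth)
        for ev, (_, row) in zip(events, truth.iterrows()):
            assert abs(ev.start_idx - row.start_idx) <= 1
            assert abs(ev.end_idx - row.end_idx) <= 1

    def test_bad_sigma_rejected(self):
        with pytest.raises(ValueError):
            detect_events(_trace_with_pulse(), 1000.0, 0.0)


class TestECD:
    def test_rectangle_100pa_100us_is_10fC(self):
        t = _trace_with_pulse(depth=100.0, length=20)  # 100 pA x 100 us
        ev = NanoporeEvent(5000, 5020, 100e-6, 0.0, 100.0)
        ecd = event_ecd(t, ev, 1000.0)
        assert ecd == pytest.approx(0.01)  # pA*s
        assert ecd * 1000 == pytest.approx(10.0)  # fC

    def test_zero_deviation_span(self):
        t = _trace_with_pulse(depth=0.0)
        assert event_ecd(t, NanoporeEvent(100, 200, 5e-4, 0, 0), 1000.0) == 0.0

    def test_offset_invariance(self):
        t = _trace_with_pulse(depth=50.0, length=40)
        ev = NanoporeEvent(5000, 5040, 2e-4, 0, 50.0)
        a = event_ecd(t, ev, 1000.0)
        t2 = CurrentTrace(t.current_pa + 250.0, FS)
        b = event_ecd(t2, ev, 1250.0)
        assert a == pytest.approx(b)

    def test_out_of_range_rejected(self):
        t = _trace_with_pulse(n=100)
        with pytest.raises(ValueError):
            event_ecd(t, NanoporeEvent(50, 200, 1e-3, 0, 0), 1000.0)


class TestCalibration:
    def test_power_law_recovered_exactly(self):
        a, b = 3.7e-5, 1.4
        standards = [(m, a * m**b) for m in [54, 130, 545, 2384]]
        calib = fit_ecd_calibration(standards)
        # log MW = intercept + slope * log ECD  ->  slope = 1/b
        assert calib.slope == pytest.approx(1 / b, rel=1e-12)

    def test_two_standards_line_through_both(self):
        calib = fit_ecd_calibration([(100.0, 0.01), (1000.0, 0.2)])
        for mw, ecd in [(100.0, 0.01), (1000.0, 0.2)]:
            got, flag = ecd_to_mw(ecd, calib)
            assert got == pytest.approx(mw, rel=1e-12)
            assert not flag

    def test_geometric_mean_maps_to_geometric_mean(self):
        calib = fit_ecd_calibration([(100.0, 0.01), (1000.0, 0.2)])
        gm_ecd = np.sqrt(0.01 * 0.2)
        got, _ = ecd_to_mw(gm_ecd, calib)
        assert got == pytest.approx(np.sqrt(100.0 * 1000.0), rel=1e-12)

    def test_non_monotone_standards_rejected(self):
        with pytest.raises(ValueError):
            fit_ecd_calibration([(100.0, 0.02), (1000.0, 0.01)])

    def test_extrapolation_flagged(self, ecd_calibration):
        lo, _ = ecd_calibration.valid_ecd_range
        _, flag = ecd_to_mw(lo / 10, ecd_calibration)
        assert flag

    def test_nonpositive_ecd_rejected(self, ecd_calibration):
        with pytest.raises(ValueError):
            ecd_to_mw(0.0, ecd_calibration)


class TestSummary:
    def test_monodisperse_events(self, ecd_calibration):
        ecd = ecd_calibration.mw_to_ecd(545.0)
        events = [NanoporeEvent(i * 100, i * 100 + 20, 1e-4, float(ecd), 1.0) for i in range(10)]
        s = events_to_mw_summary(events, ecd_calibration)
        assert s.pdi == pytest.approx(1.0, abs=1e-9)
        assert s.mw_kda == pytest.approx(545.0, rel=1e-6)

    def test_two_event_hand_arithmetic(self, ecd_calibration):
        events = [
            NanoporeEvent(0, 20, 1e-4, float(ecd_calibration.mw_to_ecd(mw)), 1.0)
            for mw in (100.0, 300.0)
        ]
        s = events_to_mw_summary(events, ecd_calibration)
        assert s.mn_kda == pytest.approx(200.0, rel=1e-9)
        assert s.mw_kda == pytest.approx(250.0, rel=1e-9)
        assert s.pdi == pytest.approx(1.25, rel=1e-9)

    def test_mw_monotone_under_ecd_inflation(self, ecd_calibration):
        rng = np.random.default_rng(2)
        ecds = rng.uniform(0.02, 0.3, 50)
        ev = [NanoporeEvent(i, i + 10, 5e-5, float(e), 1.0) for i, e in enumerate(ecds)]
        ev_big = [NanoporeEvent(i, i + 10, 5e-5, float(e * 1.3), 1.0) for i, e in enumerate(ecds)]
        s0 = events_to_mw_summary(ev, ecd_calibration)
        s1 = events_to_mw_summary(ev_big, ecd_calibration)
        assert s1.mw_kda > s0.mw_kda

    def test_no_events_rejected(self, ecd_calibration):
        with pytest.raises(ValueError):
            events_to_mw_summary([], ecd_calibration)


class TestPipeline:
    def test_snr10_precision_recall(self, ecd_calibration):
        """SNR 10, ~1000 events: precision and recall >= 0.99."""
        dist, _ = gen_mw_lognormal(1000.0, 1.5)
        trace, truth = gen_nanopore_trace(
            dist, ecd_calibration, event_rate_hz=40, duration_s=25.0, seed=7, snr=10.0
        )
        assert len(truth) >= 900
        filt = lowpass_filter(trace)
        baseline, sigma = estimate_baseline_sigma(filt)
        events = detect_events(filt, baseline, sigma)
        intervals = list(zip(truth.start_idx, truth.end_idx))
        used, tp = set(), 0
        for ev in events:
            for j, (ts, te) in enumerate(intervals):
                if j not in used and ev.start_idx < te and ts < ev.end_idx:
                    tp += 1
                    used.add(j)
                    break
        assert tp / len(events) >= 0.99  # precision
        assert tp / len(truth) >= 0.99  # recall
        # Mw recovered within 10% of the generating distribution's target
        s = events_to_mw_summary(events, ecd_calibration)
        assert s.mw_kda == pytest.approx(1000.0, rel=0.10)
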