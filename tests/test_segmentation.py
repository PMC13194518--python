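import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

from tstscore import segmentation as sg
from tstscore.io_formats import ForceTrace
from tstscore.synthetic import SimulationConfig, simulate_session


def make_trace(values, rate=80.0):
    values = np.asarray(values, dtype=float)
    return ForceTrace(1, np.arange(len(values)) / rate, values, nominal_rate=rate)


class TestHeavySmooth:
    def test_constant_preserved(self):
        out = sg.heavy_smooth(np.full(1000, 3.7))
        assert np.allclose(out, 3.7)

    def test_zero_phase_impulse_symmetry(self):
        x = np.zeros(2001)
        x[1000] = 1.0
        out = sg.heavy_smooth(x)
        assert np.allclose(out, out[::-1], atol=1e-12)

    def test_matches_forward_backward_filter_oracle(self):
        """Independent oracle: scipy's forward-backward box filter with the
        same edge-replication padding."""
        rng = np.random.default_rng(11)
        x = rng.normal(10, 2, 5000)
        w = 100
        oracle = signal.filtfilt(np.ones(w) / w, [1.0], x, padtype="constant", padlen=w)
        assert np.allclose(sg.heavy_smooth(x, w), oracle, rtol=0, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            sg.heavy_smooth(np.zeros(150))


class TestPeriodThreshold:
    def test_formula(self):
        # mean 10, min 2 -> 0.9*10 + 0.1*2 = 9.2
        assert sg.period_threshold([2.0, 10.0, 18.0]) == pytest.approx(9.2)

    def test_constant_is_fixed_point(self):
        assert sg.period_threshold(np.full(50, 4.2)) == pytest.approx(4.2)

    def test_random_series_vs_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(20, 5, 10000)
        assert sg.period_threshold(x) == pytest.approx(
            0.9 * x.mean() + 0.1 * x.min(), rel=1e-12
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty input"):
            sg.period_threshold([])


def brute_provisional(x, thr, n_persist, rate):
    for i in range(len(x) - n_persist + 1):
        if np.all(x[i : i + n_persist] > thr):
            return i / rate
    return None


class TestProvisionalStart:
    def test_clean_step(self):
        rate = 80.0
        x = np.where(np.arange(int(600 * rate)) / rate < 100.0, 1.0, 10.0)
        assert sg.provisional_start(x, 5.0, rate=rate) == pytest.approx(100.0)

    def test_short_excursion_fails_persistence(self):
        rate = 80.0
        t = np.arange(int(600 * rate)) / rate
        x = np.where(((t >= 50) & (t < 60)) | (t >= 120), 10.0, 1.0)
        assert sg.provisional_start(x, 5.0, rate=rate) == pytest.approx(120.0)

    def test_no_qualifying_period(self):
        with pytest.raises(ValueError, match="no post-start period found"):
            sg.provisional_start(np.ones(80 * 300), 5.0, rate=80.0)

    def test_random_crossings_vs_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        rate = 80.0
        persistence = 2.0  # short persistence keeps the scan exhaustive
        n_persist = int(np.ceil(persistence * rate))
        for _ in range(5):
            x = rng.normal(0, 1, 4000).cumsum() / 10
            thr = float(np.median(x))
            expected = brute_provisional(x, thr, n_persist, rate)
            if expected is None:
                with pytest.raises(ValueError):
                    sg.provisional_start(x, thr, rate=rate, persistence=persistence)
            else:
                got = sg.provisional_start(x, thr, rate=rate, persistence=persistence)
                assert got == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=25, derandomize=True)
    @given(
        seed=st.integers(0, 1000),
        bump=st.floats(min_value=0.01, max_value=2.0),
    )
    def test_monotone_in_threshold(self, seed, bump):
        """Raising the threshold never yields an earlier start."""
        rng = np.random.default_rng(seed)
        x = rng.normal(5, 1, 2000).cumsum() / 50 + 5
        rate, persistence = 80.0, 2.0
        thr = float(np.quantile(x, 0.3))
        try:
            t_low = sg.provisional_start(x, thr, rate=rate, persistence=persistence)
        except ValueError:
            return
        try:
            t_high = sg.provisional_start(x, thr + bump, rate=rate, persistence=persistence)
        except ValueError:
            return  # no qualifying period at the higher threshold
        assert t_high >= t_low


class TestBaseline:
    def test_flat_plateau_wins(self):
        rng = np.random.default_rng(0)
        seg_len = 3200
        v = rng.normal(25, 1.0, seg_len)
        # plant an exactly flat plateau inside the middle third
        lo = seg_len // 3
        v[lo + 100 : lo + 900] = 24.25
        tr = make_trace(v)
        assert sg.estimate_baseline(tr, 0.0, 800) == pytest.approx(24.25)

    def test_matches_exhaustive_window_scan(self):
        rng = np.random.default_rng(5)
        v = rng.normal(25, 0.5, 20000)
        tr = make_trace(v)
        got = sg.estimate_baseline(tr, 0.0, 800)
        lo, hi = len(v) // 3, (2 * len(v)) // 3
        wins = sliding_window_view(v[lo:hi], 800)
        expected = wins[int(np.argmin(wins.std(axis=1)))].mean()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_tie_prefers_earlier_window(self):
        v = np.zeros(3000)  # every window has SD 0: earliest must win
        lo = 1000
        v[:lo] = 5.0
        v[lo:2000] = np.linspace(3, 3, 1000)  # constant 3 in the middle third
        v[2000:] = 7.0
        tr = make_trace(v)
        assert sg.estimate_baseline(tr, 0.0, 800) == pytest.approx(3.0)

    def test_short_segment_rejected(self):
        tr = make_trace(np.ones(1000))
        with pytest.raises(ValueError, match="too short for baseline"):
            sg.estimate_baseline(tr, 0.0, 800)


class TestRefineStart:
    def test_clean_step_crossing(self):
        rate = 80.0
        t = np.arange(int(200 * rate)) / rate
        v = np.where(t < 100.0, 5.0, 25.0)
        tr = make_trace(v)
        assert sg.refine_start(tr, 24.0, 100.3) == pytest.approx(100.0)

    def test_always_above_returns_left_edge(self):
        tr = make_trace(np.full(80 * 200, 30.0))
        got = sg.refine_start(tr, 24.0, 100.0, search_margin=30.0)
        assert got == pytest.approx(70.0)

    def test_no_crossing_falls_back(self, caplog):
        tr = make_trace(np.full(80 * 200, 10.0))
        with caplog.at_level("WARNING"):
            got = sg.refine_start(tr, 24.0, 100.0)
        assert got == pytest.approx(100.0)

    def test_noisy_step_vs_brute_scan(self):
        rng = np.random.default_rng(9)
        rate = 80.0
        t = np.arange(int(200 * rate)) / rate
        v = np.where(t < 100.0, 5.0, 25.0) + rng.normal(0, 0.13, len(t))
        tr = make_trace(v)
        baseline, prov, margin = 24.9, 100.4, 30.0
        got = sg.refine_start(tr, baseline, prov, margin)
        mask = (t >= prov - margin) & (t <= prov + margin)
        expected = t[mask][np.nonzero(v[mask] > baseline)[0][0]]
        assert got == pytest.approx(expected, abs=1e-12)


class TestExtractWindow:
    def test_constant_input_gives_zero_window(self):
        tr = make_trace(np.full(80 * 400, 25.0))
        win = sg.extract_window(tr, 10.0, 25.0)
        assert np.allclose(win.values, 0.0, atol=1e-9)
        assert len(win) == 28800

    def test_passband_gain_near_unity(self):
        rate = 80.0
        t = np.arange(int(400 * rate)) / rate
        tr = make_trace(25.0 + np.sin(2 * np.pi * 5.0 * t))
        win = sg.extract_window(tr, 10.0, 25.0)
        mid = win.values[len(win) // 4 : -len(win) // 4]
        assert 0.95 <= mid.max() <= 1.05

    def test_stopband_attenuation(self):
        rate = 80.0
        t = np.arange(int(400 * rate)) / rate
        tr = make_trace(25.0 + np.sin(2 * np.pi * 0.1 * t))
        win = sg.extract_window(tr, 10.0, 25.0)
        assert np.abs(win.values[len(win) // 4 : -len(win) // 4]).max() < 0.05

    def test_truncated_recording_rejected(self):
        tr = make_trace(np.full(80 * 300, 25.0))
        with pytest.raises(ValueError, match="truncated"):
            sg.extract_window(tr, 10.0, 25.0)


class TestDetectSession:
    def test_known_hang_time_recovered(self, default_session, detected):
        seg, _ = detected
        assert abs(seg.refined_start - default_session.truth_start_s) <= 0.5

    def test_override_fixes_window(self, default_session):
        seg, win = sg.detect_session(default_session.trace, start_override=91.0)
        assert seg.window == (91.0, 451.0)
        assert seg.refined_start == 91.0
        assert len(win) == 28800

    def test_deterministic(self, default_session):
        s1, w1 = sg.detect_session(default_session.trace)
        s2, w2 = sg.detect_session(default_session.trace)
        assert s1 == s2
        assert np.array_equal(w1.values, w2.values)

    def test_refined_within_margin_of_provisional(self, detected):
        seg, _ = detected
        assert abs(seg.refined_start - seg.provisional_start) <= 30.0

    def test_window_energy_below_plateau(self, default_session, detected):
        seg, win = detected
        assert np.mean(np.abs(win.values)) < seg.baseline
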