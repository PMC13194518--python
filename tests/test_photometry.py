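import numpy as np
import pytest

from tstscore import photometry as ph
from tstscore import synthetic


def make_session(sig, ctl, rate=40.0):
    n = len(sig)
    return ph.PhotometrySession(np.arange(n) / rate, sig, ctl, rate)


def brute_prominence_peaks(x, min_prominence):
    """Exhaustive topographic-prominence scan (independent of scipy)."""
    out = []
    for i in range(1, len(x) - 1):
        if not (x[i] > x[i - 1] and x[i] > x[i + 1]):
            continue
        lmin = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            lmin = min(lmin, x[j])
            j -= 1
        rmin = x[i]
        j = i + 1
        while j < len(x) and x[j] <= x[i]:
            rmin = min(rmin, x[j])
            j += 1
        prom = x[i] - max(lmin, rmin)
        if prom >= min_prominence:
            out.append((i, prom))
    return out


class TestFitControl:
    def test_exact_linear_case(self):
        rng = np.random.default_rng(0)
        ctl = 100.0 + rng.normal(0, 5, 2000)
        sig = 2.0 * ctl + 5.0
        _, slope, intercept = ph.fit_control(make_session(sig, ctl))
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert intercept == pytest.approx(5.0, abs=1e-4)

    def test_robust_to_sparse_transients(self):
        rng = np.random.default_rng(1)
        ctl = 100.0 + rng.normal(0, 5, 4000)
        sig = 2.0 * ctl + 5.0
        bad = rng.choice(4000, size=40, replace=False)  # 1% large transients
        sig[bad] += 200.0
        _, slope_robust, _ = ph.fit_control(make_session(sig, ctl))
        slope_ols = np.polyfit(ctl, sig, 1)[0]
        assert abs(slope_robust - 2.0) <= 0.05
        assert abs(slope_robust - 2.0) < abs(slope_ols - 2.0)

    def test_constant_control_rejected(self):
        with pytest.raises(ValueError, match="degenerate control"):
            ph.fit_control(make_session(np.ones(500), np.ones(500)))


class TestComputeDff:
    def test_signal_equals_fit_gives_zero(self):
        rng = np.random.default_rng(2)
        fitted = 100.0 + rng.normal(0, 1, 1000)
        sess = make_session(fitted + rng.normal(0, 1e-9, 1000), fitted)
        dff = ph.compute_dff(sess, fitted)
        assert np.allclose(dff.dff, 0.0, atol=1e-9)

    def test_constant_dff_rejected(self):
        fitted = np.full(1000, 100.0)
        sess = make_session(1.1 * fitted, fitted)
        with pytest.raises(ValueError, match="constant dff"):
            ph.compute_dff(sess, fitted)

    def test_nonpositive_fit_rejected(self):
        sess = make_session(np.ones(200), np.ones(200))
        with pytest.raises(ValueError, match="non-positive fitted control"):
            ph.compute_dff(sess, np.linspace(-1, 1, 200))

    def test_drift_cancellation_in_quiet_epochs(self, default_session):
        sess, true_times = synthetic.simulate_photometry(
            default_session.truth_bouts, seed=20
        )
        fitted, a, b = ph.fit_control(sess)
        dff = ph.compute_dff(sess, fitted, a, b)
        # samples far from every injected transient should sit at dff ~ 0
        quiet = np.ones(len(sess), dtype=bool)
        for e in true_times:
            quiet &= ~((sess.timestamps >= e - 0.5) & (sess.timestamps <= e + 4.0))
        assert np.abs(dff.dff[quiet]).max() < 0.02

    def test_zscore_idempotent(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 2, 1000) + 5
        z1 = (x - x.mean()) / x.std()
        z2 = (z1 - z1.mean()) / z1.std()
        assert np.allclose(z1, z2, atol=1e-9)


class TestDetectPeaks:
    def test_flat_series_empty(self):
        assert len(ph.detect_peaks(np.zeros(100))) == 0

    def test_single_bump(self):
        t = np.linspace(-3, 3, 301)
        x = np.exp(-(t**2))
        peaks = ph.detect_peaks(x)
        assert len(peaks) == 1
        assert peaks.prominences[0] == pytest.approx(1.0, abs=1e-3)

    def test_matches_brute_force_prominence_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 3000)
        peaks = ph.detect_peaks(x, min_prominence=0.5)
        expected = brute_prominence_peaks(x, 0.5)
        assert np.array_equal(peaks.peak_times, [i for i, _ in expected])
        assert np.allclose(peaks.prominences, [p for _, p in expected], atol=1e-9)


class TestBoutStateSummary:
    def _constant_dff(self, bouts, value=2.0, rate=40.0):
        t0, t1 = bouts.session_span
        n = int(round((t1 - t0) * rate))
        t = t0 + np.arange(n) / rate
        rng = np.random.default_rng(0)
        raw = value + rng.normal(0, 1e-9, n)
        z = (raw - raw.mean()) / raw.std()
        return ph.DffTrace(t, raw, z, np.ones(n), 1.0, 0.0, rate)

    def test_constant_zscore_auc(self, default_session):
        bouts = default_session.truth_bouts
        t0, t1 = bouts.session_span
        rate = 40.0
        n = int(round((t1 - t0) * rate))
        t = t0 + np.arange(n) / rate
        z = np.full(n, 1.5)
        trace = ph.DffTrace.__new__(ph.DffTrace)  # bypass z-score invariant
        object.__setattr__(trace, "timestamps", t)
        object.__setattr__(trace, "dff", z)
        object.__setattr__(trace, "zscore", z)
        object.__setattr__(trace, "fitted_control", np.ones(n))
        object.__setattr__(trace, "fit_slope", 1.0)
        object.__setattr__(trace, "fit_intercept", 0.0)
        object.__setattr__(trace, "rate", rate)
        empty = ph.PeakSet(np.array([]), np.array([]), np.array([]))

        class B:
            bouts = default_session.truth_bouts.bouts

        summ = ph.bout_state_summary(trace, empty, B)
        assert np.allclose(summ["auc_per_s"], 1.5, atol=1e-6)
        assert np.all(summ["peak_freq_hz"] == 0.0)

    def test_peak_frequency(self, default_session):
        bouts = default_session.truth_bouts.bouts
        state, a, b = bouts[0]
        times = np.linspace(a + 0.1, min(b, a + 5), 3)
        peaks = ph.PeakSet(times, np.ones(3), np.ones(3))
        trace = self._constant_dff(default_session.truth_bouts)

        class B:
            bouts = default_session.truth_bouts.bouts

        summ = ph.bout_state_summary(trace, peaks, B)
        assert summ.iloc[0]["peak_freq_hz"] == pytest.approx(3.0 / (b - a))


@pytest.fixture(scope="module")
def aligned(default_session):
    sess, _ = synthetic.simulate_photometry(default_session.truth_bouts, seed=21)
    fitted, a, b = ph.fit_control(sess)
    dff = ph.compute_dff(sess, fitted, a, b)
    peaks = ph.detect_peaks(dff)

    class B:
        bouts = default_session.truth_bouts.bouts

    return dff, peaks, B, ph.align_to_onsets(dff, peaks, B)


class TestAlignToOnsets:
    def test_long_flank_rows_fully_unmasked(self, aligned, default_session):
        dff, peaks, B, mat = aligned
        bouts = default_session.truth_bouts.bouts
        for k, onset in enumerate(mat.onset_times):
            i = next(j for j, (_, a, _) in enumerate(bouts) if a == onset)
            prev_d = bouts[i - 1][2] - bouts[i - 1][1]
            cur_d = bouts[i][2] - bouts[i][1]
            if prev_d >= 2.0 and cur_d >= 2.0:
                assert mat.mask[k].all()

    def test_short_preceding_bout_masks_early_cells(self, aligned, default_session):
        dff, peaks, B, mat = aligned
        bouts = default_session.truth_bouts.bouts
        for k, onset in enumerate(mat.onset_times):
            i = next(j for j, (_, a, _) in enumerate(bouts) if a == onset)
            prev_d = bouts[i - 1][2] - bouts[i - 1][1]
            if prev_d < 1.0:
                pre = mat.rel_times < 0
                expected_masked = mat.rel_times[pre] < -prev_d - 1.0 / dff.rate
                assert not mat.mask[k][pre][expected_masked].any()

    def test_sentinel_values_never_leak_into_means(self, aligned):
        dff, peaks, B, mat = aligned
        # poison every cell that is not event-pure, re-align, compare means
        z = dff.zscore.copy()
        t = dff.timestamps
        pure = np.zeros(len(t), dtype=bool)
        n_lag = (len(mat.rel_times) - 1) // 2
        for k, onset in enumerate(mat.onset_times):
            i0 = int(np.searchsorted(t, onset))
            idx = i0 + np.arange(-n_lag, n_lag + 1)
            ok = (idx >= 0) & (idx < len(t)) & mat.mask[k]
            pure[idx[ok]] = True
        z_poisoned = np.where(pure, z, 1e6)
        trace2 = ph.DffTrace.__new__(ph.DffTrace)
        for name, val in [
            ("timestamps", t), ("dff", dff.dff), ("zscore", z_poisoned),
            ("fitted_control", dff.fitted_control), ("fit_slope", 1.0),
            ("fit_intercept", 0.0), ("rate", dff.rate),
        ]:
            object.__setattr__(trace2, name, val)
        mat2 = ph.align_to_onsets(trace2, peaks, B)
        for state in ("mobile-onset", "immobile-onset"):
            m1 = mat.column_means(state)
            m2 = mat2.column_means(state)
            ok = ~np.isnan(m1)
            assert np.allclose(m1[ok], m2[ok], atol=1e-6)

    def test_onset_coupled_transients_show_mobility_bias(self, default_session):
        sess, _ = synthetic.simulate_photometry(default_session.truth_bouts, seed=22)
        fitted, a, b = ph.fit_control(sess)
        dff = ph.compute_dff(sess, fitted, a, b)
        peaks = ph.detect_peaks(dff)

        class B:
            bouts = default_session.truth_bouts.bouts

        mat = ph.align_to_onsets(dff, peaks, B)
        st = mat.stats
        mob = st[st.event_state == "mobile-onset"]
        imm = st[st.event_state == "immobile-onset"]
        assert (mob.pre_peaks + mob.post_peaks).mean() > (
            imm.pre_peaks + imm.post_peaks
        ).mean()
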