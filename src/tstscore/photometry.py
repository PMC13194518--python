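"""Motion-corrected calcium signals aligned to behavioral bouts.

Two-channel fiber photometry records a calcium-dependent 470 nm signal
and a calcium-independent 415 nm isosbestic control at 40 Hz.  The
control is fit to the signal with robust (IRLS, bisquare) regression so
shared artifacts — slow drift, motion — cancel in

    dFF = (F - F_fitted_iso) / F_fitted_iso

which is then z-scored over the session.  Calcium transients are local
maxima with topographic prominence >= 0.5 SD.  Bout-state summaries and
event-pure peri-onset averages connect the neural signal to the
immobility/mobility bouts scored from the load cell: samples of a
peri-onset window that fall outside the flanking bouts are masked and
never contribute to any average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal as sp_signal

__all__ = [
    "PhotometrySession",
    "DffTrace",
    "PeakSet",
    "EventAlignedMatrix",
    "fit_control",
    "compute_dff",
    "detect_peaks",
    "bout_state_summary",
    "align_to_onsets",
]

MIN_PROMINENCE = 0.5  # SD units
HALF_WINDOW_S = 1.0


@dataclass(frozen=True)
class PhotometrySession:
    """Raw two-channel photometry trace on a shared session clock."""

    timestamps: np.ndarray
    signal_470: np.ndarray
    control_415: np.ndarray
    rate: float = 40.0

    def __post_init__(self):
        t = np.asarray(self.timestamps, dtype=float)
        s = np.asarray(self.signal_470, dtype=float)
        c = np.asarray(self.control_415, dtype=float)
        for name, arr in (("timestamps", t), ("signal_470", s), ("control_415", c)):
            object.__setattr__(self, name, arr)
        if not (t.shape == s.shape == c.shape):
            raise ValueError("channel lengths must match")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class DffTrace:
    """Motion-corrected dFF and its session z-score."""

    timestamps: np.ndarray
    dff: np.ndarray
    zscore: np.ndarray
    fitted_control: np.ndarray
    fit_slope: float
    fit_intercept: float
    rate: float = 40.0

    def __post_init__(self):
        z = np.asarray(self.zscore, dtype=float)
        object.__setattr__(self, "zscore", z)
        for name in ("timestamps", "dff", "fitted_control"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if abs(float(np.mean(z))) > 1e-6 or abs(float(np.std(z)) - 1.0) > 1e-6:
            raise ValueError("zscore must have mean 0 and SD 1 over the session")


@dataclass(frozen=True)
class PeakSet:
    """Detected calcium transients (times, z-height, prominence)."""

    peak_times: np.ndarray
    amplitudes: np.ndarray
    prominences: np.ndarray

    def __post_init__(self):
        for name in ("peak_times", "amplitudes", "prominences"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.peak_times) >= 2 and np.any(np.diff(self.peak_times) <= 0):
            raise ValueError("peak times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peak_times)


@dataclass(frozen=True)
class EventAlignedMatrix:
    """Events x time matrix of z-scores around bout onsets.

    ``mask`` is True where the cell is valid (event-pure and inside the
    recording); masked cells are excluded from every average.
    """

    values: np.ndarray  # (n_events, n_lags)
    mask: np.ndarray  # True = valid
    rel_times: np.ndarray  # s, window lag grid
    event_states: tuple  # per event: "mobile-onset" | "immobile-onset"
    onset_times: np.ndarray
    stats: pd.DataFrame = field(default_factory=pd.DataFrame, compare=False)

    def column_means(self, state: str | None = None) -> np.ndarray:
        """Mean over valid cells per lag, optionally for one onset type."""
        rows = np.ones(len(self.values), dtype=bool)
        if state is not None:
            rows = np.array([s == state for s in self.event_states])
        vals = np.where(self.mask[rows], self.values[rows], np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(vals, axis=0)


def fit_control(session: PhotometrySession, max_iter: int = 50, tol: float = 1e-8):
    """Robustly fit the isosbestic channel to the calcium channel.

    Iteratively reweighted least squares with Tukey bisquare weights
    (tuning constant 4.685) regresses the 470 signal on the 415 control,
    so large calcium transients are down-weighted and the fit tracks the
    shared drift.  Returns ``(fitted_control, slope, intercept)``.
    """
    if len(session) < 100:
        raise ValueError("session too short for a stable control fit")
    ctl = session.control_415
    if float(np.ptp(ctl)) == 0.0:
        raise ValueError("degenerate control channel")
    X = sm.add_constant(ctl)
    model = sm.RLM(session.signal_470, X, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=max_iter, tol=tol)
    intercept, slope = float(res.params[0]), float(res.params[1])
    fitted = slope * ctl + intercept
    return fitted, slope, intercept


def compute_dff(session: PhotometrySession, fitted_control, slope: float = np.nan,
                intercept: float = np.nan) -> DffTrace:
    """dFF = (F - F_fitted_iso)/F_fitted_iso, then session z-score."""
    fitted = np.asarray(fitted_control, dtype=float)
    if np.any(fitted <= 0):
        raise ValueError("non-positive fitted control")
    dff = (session.signal_470 - fitted) / fitted
    sd = float(np.std(dff))
    # guard against exactly-proportional channels, where the z-score is undefined
    if sd <= 1e-12 * max(1.0, float(np.max(np.abs(dff)))):
        raise ValueError("constant dff")
    z = (dff - float(np.mean(dff))) / sd
    return DffTrace(
        timestamps=session.timestamps,
        dff=dff,
        zscore=z,
        fitted_control=fitted,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        rate=session.rate,
    )


def detect_peaks(trace, timestamps=None, min_prominence: float = MIN_PROMINENCE) -> PeakSet:
    """Local maxima with topographic prominence >= ``min_prominence``.

    ``trace`` may be a :class:`DffTrace` (its z-score is used) or a bare
    series plus ``timestamps``.
    """
    if isinstance(trace, DffTrace):
        series = trace.zscore
        timestamps = trace.timestamps
    else:
        series = np.asarray(trace, dtype=float)
        if timestamps is None:
            timestamps = np.arange(len(series), dtype=float)
    if len(series) < 3:
        raise ValueError("series too short for peak detection")
    idx, props = sp_signal.find_peaks(series, prominence=min_prominence)
    return PeakSet(
        peak_times=np.asarray(timestamps)[idx],
        amplitudes=series[idx],
        prominences=props["prominences"],
    )


def bout_state_summary(dff: DffTrace, peaks: PeakSet, bouts) -> pd.DataFrame:
    """Per-bout calcium measures and their per-state (bout-wise) means.

    For each bout: z-score AUC per second (trapezoidal integral divided by
    bout duration), peak frequency (count/duration, Hz) and mean peak
    amplitude.  Returns a frame with one row per bout; group by ``state``
    for the per-state means shown in state-comparison panels.
    """
    t = dff.timestamps
    rows = []
    for state, a, b in bouts.bouts:
        m = (t >= a) & (t < b)
        if not np.any(m):
            continue
        seg_t, seg_z = t[m], dff.zscore[m]
        dur = b - a
        # normalize by the integrated span so a constant z gives exactly that
        # constant regardless of where samples fall inside the bout
        span = float(seg_t[-1] - seg_t[0])
        auc = float(np.trapezoid(seg_z, seg_t)) / span if span > 0 else float(seg_z[0])
        in_bout = (peaks.peak_times >= a) & (peaks.peak_times < b)
        n_pk = int(np.sum(in_bout))
        amp = float(np.mean(peaks.amplitudes[in_bout])) if n_pk else np.nan
        rows.append((state, a, b, dur, auc, n_pk / dur, amp))
    if not rows:
        raise ValueError("clocks not aligned")
    return pd.DataFrame(
        rows,
        columns=["state", "start_s", "end_s", "duration_s", "auc_per_s",
                 "peak_freq_hz", "peak_amplitude"],
    )


def align_to_onsets(
    dff: DffTrace,
    peaks: PeakSet,
    bouts,
    half_window: float = HALF_WINDOW_S,
) -> EventAlignedMatrix:
    """Event-pure peri-onset alignment of the z-scored calcium signal.

    Every bout transition is an onset.  For the window ``[-hw, +hw]``
    around an onset, pre-onset samples must lie inside the immediately
    preceding bout and post-onset samples inside the current bout;
    anything else (including samples beyond the recording edge) is
    masked.  Events with no valid cell are dropped.  Per-event pre/post
    peak counts and mean amplitudes (event-pure peaks only) are attached
    as ``stats``.
    """
    t = dff.timestamps
    rate = dff.rate
    n_lag = int(round(half_window * rate))
    rel = np.arange(-n_lag, n_lag + 1) / rate

    bout_list = bouts.bouts
    values, mask, states, onsets, stats = [], [], [], [], []
    for k in range(1, len(bout_list)):
        prev_state, p0, p1 = bout_list[k - 1]
        cur_state, c0, c1 = bout_list[k]
        onset = c0
        i0 = int(np.searchsorted(t, onset))
        idx = i0 + np.arange(-n_lag, n_lag + 1)
        valid = (idx >= 0) & (idx < len(t))
        row = np.full(len(rel), np.nan)
        row[valid] = dff.zscore[idx[valid]]
        times = np.full(len(rel), np.nan)
        times[valid] = t[idx[valid]]
        # event-pure: pre cells inside the preceding bout, post inside current
        pure = valid.copy()
        pre = rel < 0
        post = ~pre
        with np.errstate(invalid="ignore"):
            pure[pre] &= (times[pre] >= p0) & (times[pre] < onset)
            pure[post] &= (times[post] >= onset) & (times[post] < c1)
        if not np.any(pure):
            continue
        values.append(row)
        mask.append(pure)
        states.append("mobile-onset" if cur_state == "mobile" else "immobile-onset")
        onsets.append(onset)

        pk = peaks.peak_times
        pre_ok = (pk >= max(onset - half_window, p0)) & (pk < onset)
        post_ok = (pk >= onset) & (pk <= min(onset + half_window, c1))
        stats.append(
            (
                onset,
                states[-1],
                int(np.sum(pre_ok)),
                int(np.sum(post_ok)),
                float(np.mean(peaks.amplitudes[pre_ok])) if np.any(pre_ok) else np.nan,
                float(np.mean(peaks.amplitudes[post_ok])) if np.any(post_ok) else np.nan,
            )
        )
    if not values:
        raise ValueError("no alignable onsets")
    return EventAlignedMatrix(
        values=np.array(values),
        mask=np.array(mask),
        rel_times=rel,
        event_states=tuple(states),
        onset_times=np.array(onsets),
        stats=pd.DataFrame(
            stats,
            columns=["onset_s", "event_state", "pre_peaks", "post_peaks",
                     "pre_amplitude", "post_amplitude"],
        ),
    )
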