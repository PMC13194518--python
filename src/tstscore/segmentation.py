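"""Two-step session start detection and 360-s analysis-window extraction.

A tail-suspension recording has two force regimes: a low pre-start level
while the animal stands on the platform and a high post-start plateau once
it hangs by the tail.  Detection proceeds in two steps:

1. The raw signal is heavily smoothed (zero-phase 100-point moving
   average) and a *period threshold* ``0.9*mean + 0.1*min`` of the smoothed
   signal splits the regimes; the provisional start is the earliest time
   after which the smoothed signal stays above that threshold for at least
   270 s.
2. A quiescent *baseline* is estimated as the mean of the contiguous
   800-sample window with minimal standard deviation inside the middle
   third of the post-start segment, and the start is refined to the first
   raw sample exceeding that baseline within +/-30 s of the provisional
   start.

A 360-s window starting at the refined start is then baseline-subtracted
and band-pass filtered (1-20 Hz, zero phase) for bout scoring.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io_formats import ForceTrace

__all__ = [
    "SessionSegmentation",
    "FilteredWindow",
    "heavy_smooth",
    "period_threshold",
    "provisional_start",
    "estimate_baseline",
    "refine_start",
    "extract_window",
    "detect_session",
]

logger = logging.getLogger(__name__)

# Defaults shared with the CLI config.
SMOOTH_WINDOW_POINTS = 100
PERSISTENCE_S = 270.0
SEARCH_MARGIN_S = 30.0
BASELINE_WINDOW_POINTS = 800
BAND_HZ = (1.0, 20.0)
FILTER_ORDER = 4
WINDOW_DURATION_S = 360.0


@dataclass(frozen=True)
class SessionSegmentation:
    """Result of the two-step start detection."""

    period_threshold: float  # g
    provisional_start: float  # s
    baseline: float  # g
    refined_start: float  # s
    window: tuple  # (refined_start, refined_start + 360)

    def __post_init__(self):
        if not math.isfinite(self.baseline):
            raise ValueError("baseline must be finite")


@dataclass(frozen=True)
class FilteredWindow:
    """Baseline-subtracted, band-passed 360-s analysis window.

    ``timestamps`` are relative to the refined start and span ``[0, 360)``.
    """

    timestamps: np.ndarray
    values: np.ndarray
    rate: float

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if ts.shape != vals.shape:
            raise ValueError("timestamps and values must match")
        dur = len(ts) / self.rate
        if abs(dur - WINDOW_DURATION_S) > 1.5 / self.rate:
            raise ValueError("window duration must be 360 s within one sample")
        if abs(float(np.mean(vals))) > 0.1:
            raise ValueError("band-passed window mean must be near zero")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        return len(self.values) / self.rate


def heavy_smooth(values, window_points: int = SMOOTH_WINDOW_POINTS) -> np.ndarray:
    """Zero-phase heavy smoothing: forward-backward 100-point moving average.

    The input is padded by edge replication (``window_points`` samples each
    side), convolved with the normalized box kernel once forward and once
    backward, and trimmed.  The double pass cancels the moving average's
    group delay, so the response to a centered impulse is symmetric.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D series")
    if len(x) <= 2 * window_points:
        raise ValueError("insufficient samples for smoothing")
    kernel = np.full(window_points, 1.0 / window_points)
    pad = window_points
    xp = np.concatenate([np.full(pad, x[0]), x, np.full(pad, x[-1])])
    # forward pass: causal moving average y[i] = mean(x[i-w+1 .. i])
    fwd = np.convolve(xp, kernel)[: len(xp)]
    # backward pass: run the same causal filter on the reversed series
    bwd = np.convolve(fwd[::-1], kernel)[: len(xp)][::-1]
    return bwd[pad:-pad]


def period_threshold(smoothed) -> float:
    """Level separating pre- and post-start regimes: 0.9*mean + 0.1*min."""
    x = np.asarray(smoothed, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return 0.9 * float(np.mean(x)) + 0.1 * float(np.min(x))


def provisional_start(
    smoothed,
    threshold: float,
    rate: float = 80.0,
    persistence: float = PERSISTENCE_S,
    timestamps=None,
) -> float:
    """Earliest time after which the smoothed signal stays above `threshold`
    for at least `persistence` seconds.

    Every sample in the persistence window must be *strictly* greater than
    the threshold; the window is closed-open, ``ceil(persistence*rate)``
    samples.  Raises if no time qualifies.
    """
    x = np.asarray(smoothed, dtype=float)
    n_persist = int(math.ceil(persistence * rate))
    if len(x) < n_persist:
        raise ValueError("series shorter than the persistence window")
    above = x > threshold
    # suffix run-length of consecutive True starting at each index
    rev = above[::-1].astype(np.int64)
    idx = np.arange(len(rev))
    boundaries = np.where(rev == 0, idx, -1)
    last_zero = np.maximum.accumulate(boundaries)
    run = np.where(rev == 1, idx - last_zero, 0)[::-1]
    hits = np.nonzero(run >= n_persist)[0]
    if hits.size == 0:
        raise ValueError("no post-start period found")
    i = int(hits[0])
    if timestamps is not None:
        return float(np.asarray(timestamps, dtype=float)[i])
    return i / rate


def estimate_baseline(
    trace: ForceTrace,
    provisional_start_s: float,
    window_len: int = BASELINE_WINDOW_POINTS,
) -> float:
    """Quiescent-plateau force: mean of the minimum-SD contiguous window.

    Within the middle third of the post-start segment, every contiguous
    ``window_len``-sample window is scored by its population standard
    deviation; the mean of the lowest-SD window is returned (the earliest
    window wins exact ties).
    """
    seg = trace.values[trace.timestamps >= provisional_start_s]
    n = len(seg)
    if n < 3 * window_len:
        raise ValueError("post-start segment too short for baseline")
    lo, hi = n // 3, (2 * n) // 3  # middle third, windows fully inside
    mid = seg[lo:hi]
    if len(mid) < window_len:
        raise ValueError("post-start segment too short for baseline")
    # centering keeps the sliding variance numerically faithful
    c = mid - np.mean(mid)
    csum = np.concatenate([[0.0], np.cumsum(c)])
    csum2 = np.concatenate([[0.0], np.cumsum(c * c)])
    s1 = csum[window_len:] - csum[:-window_len]
    s2 = csum2[window_len:] - csum2[:-window_len]
    var = s2 / window_len - (s1 / window_len) ** 2
    start = int(np.argmin(var))  # argmin returns the first minimum
    return float(np.mean(mid[start : start + window_len]))


def refine_start(
    trace: ForceTrace,
    baseline: float,
    provisional_start_s: float,
    search_margin: float = SEARCH_MARGIN_S,
) -> float:
    """First raw sample strictly above `baseline` near the provisional start.

    The scan is confined to ``provisional_start +/- search_margin``; if no
    sample in that interval exceeds the baseline the provisional start is
    returned unchanged with a logged warning.
    """
    if not math.isfinite(baseline):
        raise ValueError("baseline must be finite")
    t = trace.timestamps
    lo = provisional_start_s - search_margin
    hi = provisional_start_s + search_margin
    mask = (t >= lo) & (t <= hi)
    if not np.any(mask):
        raise ValueError("empty start-refinement search interval")
    seg_t = t[mask]
    seg_v = trace.values[mask]
    hits = np.nonzero(seg_v > baseline)[0]
    if hits.size == 0:
        logger.warning(
            "no baseline crossing within +/-%.0f s; keeping provisional start",
            search_margin,
        )
        return float(provisional_start_s)
    return float(seg_t[int(hits[0])])


def bandpass_sos(rate: float, band=BAND_HZ, order: int = FILTER_ORDER):
    """Butterworth band-pass in second-order sections for `sosfiltfilt`."""
    return signal.butter(order, band, btype="bandpass", fs=rate, output="sos")


def extract_window(
    trace: ForceTrace,
    refined_start: float,
    baseline: float,
    band=BAND_HZ,
    order: int = FILTER_ORDER,
    duration: float = WINDOW_DURATION_S,
) -> FilteredWindow:
    """Slice ``[refined_start, refined_start+360)``, subtract the baseline,
    and band-pass 1-20 Hz with zero phase (forward-backward Butterworth)."""
    t = trace.timestamps
    rate = trace.rate
    i0 = int(np.searchsorted(t, refined_start))
    n = int(round(duration * rate))
    if i0 + n > len(t):
        raise ValueError("recording truncated before 360 s window")
    raw = trace.values[i0 : i0 + n] - baseline
    sos = bandpass_sos(rate, band, order)
    filtered = signal.sosfiltfilt(sos, raw)
    return FilteredWindow(
        timestamps=(t[i0 : i0 + n] - t[i0]),
        values=filtered,
        rate=rate,
    )


def detect_session(
    trace: ForceTrace,
    start_override: float | None = None,
    smoothing_points: int = SMOOTH_WINDOW_POINTS,
    persistence: float = PERSISTENCE_S,
    search_margin: float = SEARCH_MARGIN_S,
    baseline_points: int = BASELINE_WINDOW_POINTS,
    band=BAND_HZ,
    order: int = FILTER_ORDER,
    duration: float = WINDOW_DURATION_S,
):
    """Full two-step start detection plus window extraction.

    With ``start_override`` the detection steps are skipped: the window is
    exactly ``[override, override+360)`` and the baseline is estimated by
    the usual minimum-variability procedure on the post-override segment.

    Returns ``(SessionSegmentation, FilteredWindow)``.
    """
    rate = trace.rate
    if start_override is not None:
        baseline = estimate_baseline(trace, start_override, baseline_points)
        seg = SessionSegmentation(
            period_threshold=float("nan"),
            provisional_start=float(start_override),
            baseline=baseline,
            refined_start=float(start_override),
            window=(float(start_override), float(start_override) + duration),
        )
        win = extract_window(trace, start_override, baseline, band, order, duration)
        return seg, win

    smoothed = heavy_smooth(trace.values, smoothing_points)
    thr = period_threshold(smoothed)
    prov = provisional_start(
        smoothed, thr, rate=rate, persistence=persistence, timestamps=trace.timestamps
    )
    baseline = estimate_baseline(trace, prov, baseline_points)
    refined = refine_start(trace, baseline, prov, search_margin)
    seg = SessionSegmentation(
        period_threshold=thr,
        provisional_start=prov,
        baseline=baseline,
        refined_start=refined,
        window=(refined, refined + duration),
    )
    win = extract_window(trace, refined, baseline, band, order, duration)
    return seg, win
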