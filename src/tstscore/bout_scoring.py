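"""Immobility/mobility bout detection and behavioral outcome measures.

The band-passed load-cell signal oscillates around zero, so it is first
rectified into a movement envelope (rolling maximum of the absolute value
over 0.25 s).  A sample is *mobile* when the envelope exceeds the
detection threshold (in grams); maximal runs of equal state form bouts
that tile the 360-s window.  From the bouts we derive the outcome
measures used throughout the assay: total immobility time, immobility
latency, the cumulative immobility curve and per-minute immobility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import AnnotationTrack
from .segmentation import FilteredWindow, WINDOW_DURATION_S

__all__ = [
    "BoutSeries",
    "ScoreSummary",
    "movement_envelope",
    "classify_states",
    "summarize",
    "score_at_thresholds",
    "CANDIDATE_THRESHOLDS",
    "DEFAULT_THRESHOLD",
    "ENVELOPE_SPAN_S",
]

#: Candidate detection thresholds (g), chosen above the sensor noise floor.
CANDIDATE_THRESHOLDS = (0.4, 0.6, 0.8, 1.0, 1.2)
#: Cohort-calibrated global best threshold (g).
DEFAULT_THRESHOLD = 0.792
#: Envelope span (s): rolling-max support for rectifying the oscillation.
ENVELOPE_SPAN_S = 0.25


@dataclass(frozen=True)
class BoutSeries:
    """Per-sample binary state plus the derived bout intervals.

    ``immobile`` is a boolean array at the window rate; ``bouts`` are the
    maximal runs as ``(state, start_s, end_s)`` half-open intervals tiling
    ``[0, duration)``.
    """

    immobile: np.ndarray
    rate: float
    threshold_used: float
    duration: float = WINDOW_DURATION_S

    def __post_init__(self):
        imm = np.asarray(self.immobile, dtype=bool)
        object.__setattr__(self, "immobile", imm)
        if abs(len(imm) / self.rate - self.duration) > 1.5 / self.rate:
            raise ValueError("state series must cover the full window")

    @property
    def bouts(self) -> tuple:
        """Maximal equal-state runs as (state, start_s, end_s)."""
        imm = self.immobile
        edges = np.nonzero(np.diff(imm))[0] + 1
        starts = np.concatenate([[0], edges])
        ends = np.concatenate([edges, [len(imm)]])
        out = []
        for s, e in zip(starts, ends):
            state = "immobile" if imm[s] else "mobile"
            out.append((state, s / self.rate, e / self.rate))
        return tuple(out)

    @property
    def total_immobility(self) -> float:
        return int(np.sum(self.immobile)) / self.rate

    @property
    def total_mobility(self) -> float:
        # defined as the complement so immobile + mobile == duration exactly
        return self.duration - self.total_immobility

    def to_annotation(self) -> AnnotationTrack:
        return AnnotationTrack(
            source="automated",
            rate=self.rate,
            bouts=self.bouts,
            session_span=(0.0, len(self.immobile) / self.rate),
        )


@dataclass(frozen=True)
class ScoreSummary:
    """Per-subject outcome measures over the 360-s window."""

    subject_id: str
    total_immobility: float  # s
    latency: float  # s; 360 = never immobile
    cumulative_curve: np.ndarray  # immobility seconds at t = 0..360 s
    per_minute: tuple  # six immobility times (s), one per minute
    threshold_used: float  # g

    def __post_init__(self):
        if not 0 <= self.total_immobility <= WINDOW_DURATION_S + 1e-9:
            raise ValueError("total immobility outside [0, 360]")
        if self.latency > WINDOW_DURATION_S:
            raise ValueError("latency cannot exceed the session length")
        curve = np.asarray(self.cumulative_curve, dtype=float)
        object.__setattr__(self, "cumulative_curve", curve)
        if np.any(np.diff(curve) < -1e-12):
            raise ValueError("cumulative curve must be non-decreasing")
        if abs(curve[-1] - self.total_immobility) > 1e-9:
            raise ValueError("cumulative curve must end at the total")
        if abs(sum(self.per_minute) - self.total_immobility) > 1e-9:
            raise ValueError("per-minute bins must sum to the total")


def movement_envelope(window: FilteredWindow, span: float = ENVELOPE_SPAN_S) -> np.ndarray:
    """Rolling maximum of ``|filtered value|`` over a centered span.

    The support at index ``i`` is ``[i - n//2, i - n//2 + n)`` samples
    (n = round(span*rate)), clipped at the edges; output length equals the
    input length.
    """
    n = int(round(span * window.rate))
    if n < 2:
        raise ValueError("envelope span too short")
    return ndimage.maximum_filter1d(np.abs(window.values), size=n, mode="nearest")


def classify_states(
    envelope,
    threshold: float,
    rate: float,
    min_bout: float = 0.0,
) -> BoutSeries:
    """Threshold the movement envelope into an immobility state series.

    A sample is mobile iff ``envelope > threshold``.  Runs shorter than
    ``min_bout`` seconds are merged into their neighbors, shortest run
    first (earliest first among equals); the default ``min_bout=0``
    performs no merging.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    env = np.asarray(envelope, dtype=float)
    immobile = ~(env > threshold)
    min_samples = int(np.ceil(min_bout * rate))
    if min_samples > 1:
        immobile = _merge_short_runs(immobile, min_samples)
    return BoutSeries(
        immobile=immobile, rate=rate, threshold_used=float(threshold),
        duration=len(env) / rate,
    )


def _runs(x: np.ndarray):
    edges = np.nonzero(np.diff(x))[0] + 1
    starts = np.concatenate([[0], edges])
    ends = np.concatenate([edges, [len(x)]])
    return list(zip(starts, ends))


def _merge_short_runs(immobile: np.ndarray, min_samples: int) -> np.ndarray:
    """Flip runs shorter than `min_samples` into the neighboring state.

    Runs are processed shortest first, earliest first among equals, and run
    lengths are recomputed after every merge.
    """
    x = immobile.copy()
    while True:
        runs = _runs(x)
        if len(runs) <= 1:
            return x
        lengths = [e - s for s, e in runs]
        order = sorted(range(len(runs)), key=lambda i: (lengths[i], runs[i][0]))
        victim = next((i for i in order if lengths[i] < min_samples), None)
        if victim is None:
            return x
        s, e = runs[victim]
        x[s:e] = ~x[s]


def summarize(bouts: BoutSeries, subject_id: str = "") -> ScoreSummary:
    """Outcome measures: total immobility, latency, cumulative curve,
    per-minute immobility.

    Latency is the onset of the first immobile sample run (360 s when the
    session contains no immobility).  The cumulative curve is sampled at
    1-s steps, and minute bins cover ``[0,60), ..., [300,360)``.
    """
    imm = bouts.immobile
    rate = bouts.rate
    n = len(imm)
    total = int(np.sum(imm)) / rate

    first = np.nonzero(imm)[0]
    latency = (first[0] / rate) if first.size else WINDOW_DURATION_S

    counts = np.concatenate([[0], np.cumsum(imm)])
    sec_idx = np.minimum((np.arange(0, 361) * rate).round().astype(int), n)
    curve = counts[sec_idx] / rate

    minute_edges = np.minimum((np.arange(7) * 60 * rate).round().astype(int), n)
    per_minute = tuple(
        float((counts[minute_edges[k + 1]] - counts[minute_edges[k]]) / rate)
        for k in range(6)
    )
    return ScoreSummary(
        subject_id=str(subject_id),
        total_immobility=total,
        latency=float(latency),
        cumulative_curve=curve,
        per_minute=per_minute,
        threshold_used=bouts.threshold_used,
    )


def score_at_thresholds(window: FilteredWindow, thresholds=CANDIDATE_THRESHOLDS):
    """Automated immobility time at each candidate threshold.

    Returns a list of ``(threshold, auto_time_s)`` rows; auto time is
    non-decreasing in the threshold because raising the threshold can only
    reclassify mobile samples as immobile.
    """
    thresholds = list(thresholds)
    if not thresholds or any(t <= 0 for t in thresholds):
        raise ValueError("thresholds must be non-empty and positive")
    env = movement_envelope(window)
    rows = []
    for th in thresholds:
        series = classify_states(env, th, window.rate)
        rows.append((float(th), series.total_immobility))
    return rows
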