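"""Readers and writers for every external artifact the pipeline touches.

All on-disk formats are delimited text (comma separated, ``.`` decimal,
UTF-8, one header row) or single-sheet XLSX.  Force values are converted
to grams once, at this boundary; everything downstream works in grams.
Time is in seconds, zero-based at recording start, and bout intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ForceTrace",
    "FrameTimeMap",
    "AnnotationTrack",
    "read_force_log",
    "write_force_log",
    "read_frame_time_map",
    "write_frame_time_map",
    "read_annotation",
    "write_annotation",
    "write_score_report",
    "read_score_report",
    "read_photometry",
    "write_photometry",
]

#: States a bout may take; adjacent bouts must alternate.
STATES = ("immobile", "mobile")


@dataclass(frozen=True)
class ForceTrace:
    """Calibrated force samples from one load-cell channel.

    Parameters
    ----------
    channel_id : int
        Load-cell channel, 1-4.
    timestamps : ndarray
        Seconds from recording start, strictly increasing.
    values : ndarray
        Force in grams.
    nominal_rate : float
        Nominal sampling rate in Hz (80 for the stock firmware).
    """

    channel_id: int
    timestamps: np.ndarray
    values: np.ndarray
    nominal_rate: float = 80.0

    def __post_init__(self):
        ts = np.asarray(self.timestamps, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "timestamps", ts)
        object.__setattr__(self, "values", vals)
        if not 1 <= int(self.channel_id) <= 4:
            raise ValueError("channel_id must be in 1..4")
        if ts.shape != vals.shape or ts.ndim != 1:
            raise ValueError("timestamps and values must be 1-D and equal length")
        if len(ts) >= 2:
            if np.any(np.diff(ts) <= 0):
                raise ValueError("corrupt timebase")
            if self.nominal_rate <= 0:
                raise ValueError("nominal_rate must be positive")
            med = float(np.median(np.diff(ts)))
            if abs(med - 1.0 / self.nominal_rate) > 0.2 / self.nominal_rate:
                raise ValueError(
                    "median sampling interval inconsistent with nominal rate"
                )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def rate(self) -> float:
        """Empirical rate (1 / median interval), snapped to the nominal rate
        when they agree to 0.01% so downstream duration arithmetic is exact."""
        if len(self.timestamps) < 2:
            return self.nominal_rate
        emp = 1.0 / float(np.median(np.diff(self.timestamps)))
        if abs(emp - self.nominal_rate) <= 1e-4 * self.nominal_rate:
            return self.nominal_rate
        return emp


@dataclass(frozen=True)
class FrameTimeMap:
    """Mapping from 0-based video frame indices to seconds."""

    frame_indices: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self):
        fi = np.asarray(self.frame_indices, dtype=int)
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "frame_indices", fi)
        object.__setattr__(self, "timestamps", ts)
        if fi.shape != ts.shape or fi.ndim != 1:
            raise ValueError("frame_indices and timestamps must match")
        if len(fi) == 0 or fi[0] != 0 or np.any(np.diff(fi) <= 0):
            raise ValueError("frame indices must increase strictly from 0")
        if np.any(np.diff(ts) < 0):
            raise ValueError("timestamps must be non-decreasing")

    def frame_to_time(self, frame: int | np.ndarray) -> np.ndarray:
        """Time of `frame`; frames past the map extrapolate at the mean rate."""
        frame = np.asarray(frame)
        return np.interp(frame, self.frame_indices, self.timestamps)


@dataclass(frozen=True)
class AnnotationTrack:
    """Binary immobility/mobility bouts tiling one session span.

    ``bouts`` is an ordered list of ``(state, start_s, end_s)`` half-open
    intervals that tile ``session_span`` with alternating states.
    """

    source: str  # "manual" | "automated"
    rate: float  # native sampling rate, Hz (30 video, 80 sensor)
    bouts: tuple = field(default_factory=tuple)
    session_span: tuple = (0.0, 360.0)

    def __post_init__(self):
        if self.source not in ("manual", "automated"):
            raise ValueError("source must be 'manual' or 'automated'")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        bouts = tuple(
            (str(s), float(a), float(b)) for s, a, b in self.bouts
        )
        object.__setattr__(self, "bouts", bouts)
        span = (float(self.session_span[0]), float(self.session_span[1]))
        object.__setattr__(self, "session_span", span)
        if not bouts:
            raise ValueError("annotation track needs at least one bout")
        tol = 1e-9
        prev_end = span[0]
        prev_state = None
        for state, a, b in bouts:
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            if b - a <= 0:
                raise ValueError("bout durations must be positive")
            if a < prev_end - tol:
                raise ValueError("overlapping annotation")
            if a > prev_end + tol:
                raise ValueError("non-tiling annotation")
            if state == prev_state:
                raise ValueError("adjacent bouts must alternate states")
            prev_end, prev_state = b, state
        if abs(prev_end - span[1]) > tol:
            raise ValueError("non-tiling annotation")

    @property
    def duration(self) -> float:
        return self.session_span[1] - self.session_span[0]

    def total_time(self, state: str = "immobile") -> float:
        """Total seconds spent in `state` (sum of bout durations)."""
        return float(sum(b - a for s, a, b in self.bouts if s == state))

    def state_at(self, t: float | np.ndarray) -> np.ndarray:
        """Binary immobility (1 = immobile) at arbitrary times in the span."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        starts = np.array([a for _, a, _ in self.bouts])
        states = np.array([s == "immobile" for s, _, _ in self.bouts])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(starts) - 1)
        return states[idx].astype(int)

    def sample_times(self) -> np.ndarray:
        """Native sample instants: t0 + k/rate covering the span."""
        t0, t1 = self.session_span
        n = int(round((t1 - t0) * self.rate))
        return t0 + np.arange(n) / self.rate

    def to_series(self) -> np.ndarray:
        """Per-sample binary immobility at the native rate."""
        return self.state_at(self.sample_times())

    def window(self, start: float, duration: float) -> "AnnotationTrack":
        """Clip to ``[start, start + duration)`` and rebase time to 0.

        Used to re-express tracks recorded on different clocks (video vs
        extracted analysis window) in shared window coordinates.
        """
        end = start + duration
        bouts = []
        for state, a, b in self.bouts:
            a2, b2 = max(a, start), min(b, end)
            if b2 - a2 > 0:
                bouts.append((state, a2 - start, b2 - start))
        if not bouts:
            raise ValueError("window does not overlap the track")
        return AnnotationTrack(
            source=self.source,
            rate=self.rate,
            bouts=bouts,
            session_span=(bouts[0][1], bouts[-1][2]),
        )


# ---------------------------------------------------------------------------
# Load-cell logs
# ---------------------------------------------------------------------------

def read_force_log(path, channel: int, nominal_rate: float = 80.0) -> ForceTrace:
    """Read one channel of a load-cell CSV log.

    The log has columns ``time_s, ch1..chN`` (N <= 4) and an optional second
    header row giving units (``mg`` values are divided by 1000; ``g`` values
    pass through).  Timestamps are normalized to start at the file's first
    timestamp.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    col = f"ch{int(channel)}"
    if col not in df.columns:
        raise ValueError("channel not found")
    scale = 1.0
    if len(df) and not _is_number(df.iloc[0]["time_s"]):
        unit = str(df.iloc[0][col]).strip().lower()
        scale = 1e-3 if unit == "mg" else 1.0
        df = df.iloc[1:].reset_index(drop=True)
    df = df.astype(float)
    if len(df) < 2:
        raise ValueError("empty log")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError("corrupt timebase")
    return ForceTrace(
        channel_id=int(channel),
        timestamps=t - t[0],
        values=df[col].to_numpy() * scale,
        nominal_rate=nominal_rate,
    )


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_force_log(path, traces: Sequence[ForceTrace], units: str = "g") -> None:
    """Write one or more equal-length channels as a load-cell CSV log."""
    traces = list(traces)
    if not traces:
        raise ValueError("nothing to write")
    t = traces[0].timestamps
    data = {"time_s": t}
    for tr in traces:
        if len(tr) != len(t):
            raise ValueError("channels must share a timebase")
        vals = tr.values * (1000.0 if units == "mg" else 1.0)
        data[f"ch{tr.channel_id}"] = vals
    df = pd.DataFrame(data)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(df.columns) + "\n")
        fh.write(",".join(["s"] + [units] * (len(df.columns) - 1)) + "\n")
        df.to_csv(fh, index=False, header=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Frame-time maps
# ---------------------------------------------------------------------------

def read_frame_time_map(path) -> FrameTimeMap:
    """Read a ``frame,time_s`` CSV written alongside the video."""
    df = pd.read_csv(path)
    return FrameTimeMap(
        frame_indices=df["frame"].to_numpy(int),
        timestamps=df["time_s"].to_numpy(float),
    )


def write_frame_time_map(path, fmap: FrameTimeMap) -> None:
    pd.DataFrame(
        {"frame": fmap.frame_indices, "time_s": fmap.timestamps}
    ).to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

def read_annotation(
    path,
    frame_map: FrameTimeMap | None = None,
    source: str = "manual",
    rate: float | None = None,
) -> AnnotationTrack:
    """Read a bout annotation table (CSV or XLSX).

    Accepts either time columns ``state, start_s, end_s`` or frame columns
    ``state, start_frame, end_frame`` plus a :class:`FrameTimeMap` to convert
    frames to seconds.  The returned track is validated (tiling, alternation).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if {"start_s", "end_s"} <= set(df.columns):
        starts = df["start_s"].to_numpy(float)
        ends = df["end_s"].to_numpy(float)
        native_rate = rate if rate is not None else 80.0
    elif {"start_frame", "end_frame"} <= set(df.columns):
        if frame_map is None:
            raise ValueError("frame-based annotation requires a frame-time map")
        starts = np.asarray(frame_map.frame_to_time(df["start_frame"].to_numpy(int)))
        ends = np.asarray(frame_map.frame_to_time(df["end_frame"].to_numpy(int)))
        dt = np.diff(frame_map.timestamps)
        native_rate = rate if rate is not None else 1.0 / float(np.median(dt))
    else:
        raise ValueError("annotation needs start_s/end_s or start_frame/end_frame")
    bouts = list(zip(df["state"].astype(str), starts, ends))
    span = (float(starts[0]), float(ends[-1]))
    return AnnotationTrack(source=source, rate=native_rate, bouts=bouts, session_span=span)


def write_annotation(path, track: AnnotationTrack, subject: str = "") -> None:
    df = pd.DataFrame(
        [(subject, s, a, b) for s, a, b in track.bouts],
        columns=["subject", "state", "start_s", "end_s"],
    )
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Score reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = (
    "subject",
    "total_immobility_s",
    "latency_s",
    "min1_s",
    "min2_s",
    "min3_s",
    "min4_s",
    "min5_s",
    "min6_s",
    "threshold_g",
)


def write_score_report(summaries, path) -> None:
    """Write per-subject score summaries (one row each) as CSV or XLSX.

    Column order is fixed: subject id, total immobility, latency, the six
    per-minute immobility times, and the threshold used.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("nothing to write")
    rows = []
    for s in summaries:
        rows.append(
            (s.subject_id, s.total_immobility, s.latency, *s.per_minute, s.threshold_used)
        )
    df = pd.DataFrame(rows, columns=list(REPORT_COLUMNS))
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False, float_format="%.12g")


def read_score_report(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path)
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Photometry traces
# ---------------------------------------------------------------------------

def read_photometry(path):
    """Read a two-channel photometry CSV (``time_s, sig_470, ctl_415``).

    A single-stream export with an ``led_state`` column (470/415 interleaved)
    is deinterleaved: each LED's samples keep their own timestamps and the
    415 channel is nearest-neighbor aligned onto the 470 clock.
    """
    from .photometry import PhotometrySession  # local import avoids a cycle

    df = pd.read_csv(path)
    if {"sig_470", "ctl_415"} <= set(df.columns):
        t = df["time_s"].to_numpy(float)
        sig = df["sig_470"].to_numpy(float)
        ctl = df["ctl_415"].to_numpy(float)
    elif {"led_state", "signal"} <= set(df.columns):
        sig_rows = df[df["led_state"] == 470]
        ctl_rows = df[df["led_state"] == 415]
        t = sig_rows["time_s"].to_numpy(float)
        sig = sig_rows["signal"].to_numpy(float)
        tc = ctl_rows["time_s"].to_numpy(float)
        vc = ctl_rows["signal"].to_numpy(float)
        idx = np.clip(np.searchsorted(tc, t), 0, len(tc) - 1)
        left = np.clip(idx - 1, 0, len(tc) - 1)
        use_left = np.abs(tc[left] - t) <= np.abs(tc[idx] - t)
        ctl = vc[np.where(use_left, left, idx)]
    else:
        raise ValueError("photometry needs sig_470/ctl_415 or led_state/signal")
    rate = 1.0 / float(np.median(np.diff(t)))
    return PhotometrySession(timestamps=t, signal_470=sig, control_415=ctl, rate=rate)


def write_photometry(path, session) -> None:
    pd.DataFrame(
        {
            "time_s": session.timestamps,
            "sig_470": session.signal_470,
            "ctl_415": session.control_415,
        }
    ).to_csv(path, index=False, float_format="%.12g")
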