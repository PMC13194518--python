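"""Agreement between binary scoring tracks sampled at different rates.

Sensor scoring runs at 80 Hz while video-based manual annotation is
limited to the 30 fps camera, so tracks are first resampled onto a common
grid at the finest native step using nearest-neighbor assignment (which
keeps the series strictly binary).  On that grid we count the confusion
matrix with *immobile* as the positive class and report precision,
recall, F1 and Cohen's kappa

    kappa = (Po - Pe) / (1 - Pe)

with Po the observed agreement and Pe the agreement expected from the
marginal class frequencies — the chance correction matters because
immobility and mobility are naturally imbalanced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationTrack

__all__ = [
    "AgreementReport",
    "resample_to_grid",
    "confusion",
    "precision_recall",
    "f1",
    "kappa",
    "compare_methods",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgreementReport:
    """Confusion counts and agreement metrics on the common grid."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    kappa: float
    po: float
    pe: float
    grid_step: float  # s

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        for name in ("precision", "recall", "f1", "po", "pe"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} outside [0, 1]")
        if self.kappa > 1.0 + 1e-12:
            raise ValueError("kappa cannot exceed 1")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _nearest_indices(grid_times: np.ndarray, native_times: np.ndarray) -> np.ndarray:
    """Index of the native sample nearest each grid time (ties -> earlier)."""
    idx = np.searchsorted(native_times, grid_times)
    idx = np.clip(idx, 1, len(native_times) - 1)
    left = idx - 1
    d_left = grid_times - native_times[left]
    d_right = native_times[idx] - grid_times
    take_left = d_left <= d_right  # tie resolves to the earlier sample
    out = np.where(take_left, left, idx)
    # grid times before the first native sample map to it
    out[grid_times <= native_times[0]] = 0
    return out


def resample_to_grid(tracks):
    """Resample >= 2 tracks onto the common grid at the finest native step.

    Tracks must cover the same session span to within one native step;
    they are truncated to the overlapping span before gridding.  Each grid
    point takes the state of its nearest native sample.

    Returns ``(list of binary arrays, grid_step_s)``.
    """
    tracks = list(tracks)
    if len(tracks) < 2:
        raise ValueError("need at least two tracks")
    steps = [1.0 / t.rate for t in tracks]
    t0 = max(t.session_span[0] for t in tracks)
    t1 = min(t.session_span[1] for t in tracks)
    for tr in tracks:
        tol = 1.0 / tr.rate
        if tr.session_span[0] > t0 + tol or tr.session_span[1] < t1 - tol:
            raise ValueError("unaligned session spans")
        if abs(tr.session_span[0] - t0) > tol or abs(tr.session_span[1] - t1) > tol:
            raise ValueError("unaligned session spans")
    grid_step = min(steps)
    n = int(round((t1 - t0) / grid_step))
    grid_times = t0 + np.arange(n) * grid_step
    out = []
    for tr in tracks:
        native_times = tr.sample_times()
        native_states = tr.to_series()
        keep = (native_times >= t0 - 1e-12) & (native_times < t1 + 1e-12)
        nt, ns = native_times[keep], native_states[keep]
        out.append(ns[_nearest_indices(grid_times, nt)])
    return out, grid_step


def confusion(pred, ref):
    """Confusion counts with immobile (1) as the positive class."""
    p = np.asarray(pred).astype(bool)
    r = np.asarray(ref).astype(bool)
    if p.shape != r.shape:
        raise ValueError("unaligned series")
    tp = int(np.sum(p & r))
    fp = int(np.sum(p & ~r))
    fn = int(np.sum(~p & r))
    tn = int(np.sum(~p & ~r))
    return tp, fp, fn, tn


def precision_recall(tp: int, fp: int, fn: int):
    """Precision and recall; zero denominators map to 0 with a warning."""
    if tp + fp == 0:
        logger.warning("no predicted positives; precision set to 0")
        prec = 0.0
    else:
        prec = tp / (tp + fp)
    if tp + fn == 0:
        logger.warning("no reference positives; recall set to 0")
        rec = 0.0
    else:
        rec = tp / (tp + fn)
    return prec, rec


def f1(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall; 0 when TP = 0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp == 0 and fp == 0 and fn == 0:
        raise ValueError("empty comparison")
    if tp == 0:
        return 0.0
    prec, rec = precision_recall(tp, fp, fn)
    return 2.0 * prec * rec / (prec + rec)


def kappa(pred, ref) -> float:
    """Cohen's kappa, chance-corrected agreement for two binary series.

    Returns 1 when observed agreement is perfect, including the degenerate
    case where the expected agreement is also 1.
    """
    p = np.asarray(pred).astype(bool)
    r = np.asarray(ref).astype(bool)
    if p.shape != r.shape:
        raise ValueError("unaligned series")
    n = p.size
    if n < 2:
        raise ValueError("need at least two samples")
    po = float(np.mean(p == r))
    p1, r1 = float(np.mean(p)), float(np.mean(r))
    pe = p1 * r1 + (1 - p1) * (1 - r1)
    if po >= 1.0:
        return 1.0
    if pe >= 1.0:
        return 0.0
    return (po - pe) / (1.0 - pe)


def _report(pred, ref, grid_step: float) -> AgreementReport:
    tp, fp, fn, tn = confusion(pred, ref)
    prec, rec = precision_recall(tp, fp, fn)
    score = f1(tp, fp, fn) if (tp + fp + fn) else 0.0
    k = kappa(pred, ref)
    n = tp + fp + fn + tn
    po = (tp + tn) / n
    p1 = (tp + fp) / n
    r1 = (tp + fn) / n
    pe = p1 * r1 + (1 - p1) * (1 - r1)
    return AgreementReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=prec, recall=rec, f1=score, kappa=k,
        po=po, pe=pe, grid_step=grid_step,
    )


def compare_methods(reference: AnnotationTrack, candidates: dict):
    """Score every candidate track against the manual reference.

    ``candidates`` maps method name to AnnotationTrack.  All tracks are
    resampled together onto the common grid; each candidate gets an
    :class:`AgreementReport` plus the absolute error of its total
    immobility time (seconds, from the native bout durations).  Ordering
    follows the input.
    """
    names = list(candidates)
    if not names:
        raise ValueError("no candidate tracks")
    series, grid_step = resample_to_grid([reference] + [candidates[k] for k in names])
    ref_series = series[0]
    ref_total = reference.total_time("immobile")
    out = {}
    for name, cand_series in zip(names, series[1:]):
        rep = _report(cand_series, ref_series, grid_step)
        err = abs(candidates[name].total_time("immobile") - ref_total)
        out[name] = {"report": rep, "mae_s": err}
    return out
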