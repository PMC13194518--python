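"""Ground-truthed synthetic sessions for every stage of the pipeline.

The generator emulates the morphology of a tail-suspension load-cell
recording: a low standing baseline while the mouse is on the platform, a
fast step to the suspended-weight plateau at a known hang time, and an
alternating renewal process of mobile (struggle) and immobile epochs.
Struggles are amplitude-modulated band-limited noise (2-10 Hz, inside
the 1-20 Hz analysis band); sensor noise is Gaussian with SD 0.13 g,
giving roughly +/-0.4 g excursions.  Manual annotation is emulated by
jittering the true bout boundaries and snapping them to the 30 fps frame
grid.  Photometry traces carry a shared multiplicative drift on both
channels plus additive exponential calcium transients, coupled to
mobility, on the 470 nm channel only.

Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .io_formats import AnnotationTrack, ForceTrace
from .photometry import PhotometrySession

__all__ = [
    "SimulationConfig",
    "SyntheticSession",
    "draw_bout_schedule",
    "simulate_session",
    "simulate_manual_annotation",
    "simulate_cohort",
    "simulate_photometry",
    "shift_track",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one synthetic session.

    Defaults mirror the recording conditions of the assay: 80 Hz sampling,
    ~25 g animals, +/-0.4 g sensor noise (Gaussian SD 0.13 g), 360 s
    observation window, and exponential bout durations targeting ~55%
    immobility (a typical saline level).
    """

    seed: int = 0
    rate: float = 80.0  # Hz
    hang_time_s: float = 90.0  # end of the standing (pre-start) period
    weight_g: float = 25.0  # suspended-weight plateau
    standing_force_fraction: float = 0.1  # tail force while standing
    noise_sd_g: float = 0.13  # sensor noise SD
    burst_band_hz: tuple = (2.0, 10.0)  # struggle frequency content
    burst_amplitude_g: float = 4.0  # SD of a full-strength struggle
    weak_burst_prob: float = 0.2  # fraction of weak (near-threshold) struggling
    weak_burst_range: tuple = (0.05, 0.35)  # weak amplitude, rel. to full
    am_tile_s: float = 0.5  # amplitude-modulation tile length
    mean_immobile_s: float = 10.0  # renewal-model mean per state
    immobility_fraction_target: float = 0.55
    rise_time_s: float = 0.2  # standing -> hanging transition
    window_s: float = 360.0
    post_margin_s: float = 30.0  # recording continues past the window

    def __post_init__(self):
        if min(self.hang_time_s, self.mean_immobile_s, self.rise_time_s,
               self.window_s, self.post_margin_s) <= 0:
            raise ValueError("invalid simulation config")
        if not 0 < self.immobility_fraction_target < 1:
            raise ValueError("invalid simulation config")
        lo, hi = self.burst_band_hz
        if not (1.0 < lo < hi < 20.0):
            raise ValueError("invalid simulation config")
        if self.noise_sd_g < 0 or self.burst_amplitude_g < 0:
            raise ValueError("invalid simulation config")

    @property
    def mean_mobile_s(self) -> float:
        f = self.immobility_fraction_target
        return self.mean_immobile_s * (1.0 - f) / f

    @property
    def duration_s(self) -> float:
        return self.hang_time_s + self.window_s + self.post_margin_s


@dataclass(frozen=True)
class SyntheticSession:
    """A simulated recording plus its generating ground truth."""

    trace: ForceTrace
    truth_start_s: float
    truth_bouts: AnnotationTrack
    truth_total_immobility_s: float
    config: SimulationConfig = field(compare=False, default=None)


def draw_bout_schedule(rng, span: tuple, mean_immobile: float, mean_mobile: float,
                       first_state: str = "mobile"):
    """Alternating renewal schedule of exponential bouts tiling `span`.

    The final bout is truncated at the span end.  Suspended mice struggle
    first, so the schedule starts mobile by default.
    """
    t0, t1 = span
    bouts = []
    t = t0
    state = first_state
    while t < t1:
        mean = mean_immobile if state == "immobile" else mean_mobile
        dur = rng.exponential(mean)
        end = min(t + dur, t1)
        if end > t:
            bouts.append((state, t, end))
        t = end
        state = "mobile" if state == "immobile" else "immobile"
    return bouts


def _band_noise(rng, n: int, rate: float, band) -> np.ndarray:
    """Unit-SD band-limited Gaussian noise."""
    white = rng.standard_normal(n)
    sos = sp_signal.butter(4, band, btype="bandpass", fs=rate, output="sos")
    x = sp_signal.sosfiltfilt(sos, white)
    sd = float(np.std(x))
    return x / sd if sd > 0 else x


def simulate_session(config: SimulationConfig) -> SyntheticSession:
    """One load-cell session with known start time and bout schedule."""
    rng = np.random.default_rng(config.seed)
    rate = config.rate
    n = int(round(config.duration_s * rate))
    t = np.arange(n) / rate

    standing = config.standing_force_fraction * config.weight_g
    # standing level, linear rise over rise_time_s, then the weight plateau
    base = np.interp(
        t,
        [0.0, config.hang_time_s, config.hang_time_s + config.rise_time_s, t[-1]],
        [standing, standing, config.weight_g, config.weight_g],
    )

    span = (config.hang_time_s, config.hang_time_s + config.window_s)
    bouts = draw_bout_schedule(
        rng, span, config.mean_immobile_s, config.mean_mobile_s
    )
    truth = AnnotationTrack(source="manual", rate=rate, bouts=bouts, session_span=span)

    mobile_mask = np.zeros(n, dtype=bool)
    for state, a, b in bouts:
        if state == "mobile":
            i0, i1 = int(np.ceil(a * rate)), int(np.ceil(b * rate))
            mobile_mask[i0:i1] = True
    bursts = _band_noise(rng, n, rate, config.burst_band_hz)
    # amplitude modulation: mostly full-strength struggling with a fraction
    # of weak, near-threshold bouts of effort, in 0.5-s tiles
    tile = max(1, int(round(config.am_tile_s * rate)))
    n_tiles = -(-n // tile)
    lo, hi = config.weak_burst_range
    weak = rng.random(n_tiles) < config.weak_burst_prob
    tile_amp = np.where(
        weak, rng.uniform(lo, hi, n_tiles), 1.0
    ) * config.burst_amplitude_g
    am = np.repeat(tile_amp, tile)[:n]
    values = (
        base
        + rng.normal(0.0, config.noise_sd_g, n)
        + am * bursts * mobile_mask
    )
    trace = ForceTrace(channel_id=1, timestamps=t, values=values, nominal_rate=rate)
    return SyntheticSession(
        trace=trace,
        truth_start_s=config.hang_time_s,
        truth_bouts=truth,
        truth_total_immobility_s=truth.total_time("immobile"),
        config=config,
    )


def simulate_manual_annotation(
    truth_bouts: AnnotationTrack,
    fps: float = 30.0,
    onset_jitter_sd_s: float = 0.1,
    seed: int = 0,
    max_retries: int = 100,
) -> AnnotationTrack:
    """Observer-style annotation: jittered boundaries snapped to frames.

    Internal bout boundaries get truncated-Gaussian jitter (never larger
    than half the shorter adjacent bout, so bouts never reorder) and are
    then snapped to the ``fps`` frame grid anchored at the span start.
    """
    if onset_jitter_sd_s < 0:
        raise ValueError("jitter must be non-negative")
    rng = np.random.default_rng(seed)
    t0, t1 = truth_bouts.session_span
    boundaries = np.array([a for _, a, _ in truth_bouts.bouts][1:])
    durs = np.array([b - a for _, a, b in truth_bouts.bouts])

    for _ in range(max_retries):
        jit = np.zeros(len(boundaries))
        if onset_jitter_sd_s > 0:
            for i in range(len(boundaries)):
                lim = 0.5 * min(durs[i], durs[i + 1])
                j = rng.normal(0.0, onset_jitter_sd_s)
                jit[i] = np.clip(j, -lim, lim)
        moved = boundaries + jit
        snapped = t0 + np.round((moved - t0) * fps) / fps
        edges = np.concatenate([[t0], snapped, [t1]])
        if np.all(np.diff(edges) > 0):
            states = [s for s, _, _ in truth_bouts.bouts]
            bouts = [
                (states[i], edges[i], edges[i + 1]) for i in range(len(states))
            ]
            return AnnotationTrack(
                source="manual", rate=fps, bouts=bouts, session_span=(t0, t1)
            )
    raise ValueError("could not jitter annotation without reordering bouts")


def simulate_cohort(
    n: int = 16,
    treatment_effect: float = 0.0,
    base_config: SimulationConfig | None = None,
    seed: int = 0,
    fps: float = 30.0,
    onset_jitter_sd_s: float = 0.1,
):
    """A cohort of sessions plus matching manual tracks.

    The second half of the cohort is "treated": its immobility-fraction
    target is reduced by the relative ``treatment_effect`` (0.4 mimics an
    antidepressant-scale reduction).  Per-subject seeds derive from
    ``seed`` and are recorded in each subject's config.
    """
    if n < 2:
        raise ValueError("cohort needs at least two subjects")
    base = base_config if base_config is not None else SimulationConfig()
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        treated = i >= n // 2
        frac = base.immobility_fraction_target
        if treated:
            frac = frac * (1.0 - treatment_effect)
        cfg = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            weight_g=float(rng.uniform(20.0, 30.0)),
            hang_time_s=float(rng.uniform(60.0, 180.0)),
            immobility_fraction_target=float(frac),
        )
        session = simulate_session(cfg)
        manual = simulate_manual_annotation(
            session.truth_bouts,
            fps=fps,
            onset_jitter_sd_s=onset_jitter_sd_s,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        subjects.append(
            {
                "subject_id": f"M{i + 1:02d}",
                "treated": treated,
                "session": session,
                "manual": manual,
            }
        )
    return subjects


def _transient_kernel(rate: float, rise_s: float = 0.05, decay_s: float = 0.5):
    """Unit-peak calcium transient: exponential rise times decay."""
    t = np.arange(0, 6 * decay_s, 1.0 / rate)
    k = (1.0 - np.exp(-t / rise_s)) * np.exp(-t / decay_s)
    return k / k.max()


def simulate_photometry(
    truth_bouts: AnnotationTrack,
    rate: float = 40.0,
    transient_amp: float = 0.05,
    seed: int = 0,
    signal_level: float = 150.0,
    control_level: float = 100.0,
    noise_sd: float = 0.05,
    mobile_rate_hz: float = 0.4,
    immobile_rate_hz: float = 0.05,
    onset_transient: bool = True,
    min_separation_s: float = 1.0,
    drift_model: str = "default",
):
    """Two-channel photometry coupled to the behavioral schedule.

    Both channels share a slow multiplicative drift; calcium transients
    (Poisson-timed within bouts at a state-dependent rate, thinned to a
    ``min_separation_s`` refractory, plus one at every mobility onset) are
    added to the 470 nm channel only, with fractional amplitude
    ``transient_amp``.  Returns ``(PhotometrySession, true_transient_times)``.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = truth_bouts.session_span
    n = int(round((t1 - t0) * rate))
    t = t0 + np.arange(n) / rate

    if drift_model == "none":
        drift = np.ones(n)
    else:
        rel = t - t0
        drift = np.exp(-rel / 2000.0) * (1.0 + 0.03 * np.sin(2 * np.pi * rel / 120.0))

    events = []
    for state, a, b in truth_bouts.bouts:
        lam = mobile_rate_hz if state == "mobile" else immobile_rate_hz
        k = rng.poisson(lam * (b - a))
        events.extend(rng.uniform(a, b, size=k))
        if onset_transient and state == "mobile":
            events.append(a + rng.uniform(0.0, 0.1))
    events = np.sort(np.asarray(events, dtype=float))
    kept = []
    for e in events:
        if not kept or e - kept[-1] >= min_separation_s:
            kept.append(e)
    true_times = np.array(kept)

    kernel = _transient_kernel(rate)
    transients = np.zeros(n)
    for e in true_times:
        i0 = int(np.round((e - t0) * rate))
        seg = min(len(kernel), n - i0)
        if seg > 0:
            transients[i0 : i0 + seg] += kernel[:seg]

    sig = signal_level * drift + transient_amp * signal_level * transients
    sig = sig + rng.normal(0.0, noise_sd, n)
    ctl = control_level * drift + rng.normal(0.0, noise_sd, n)
    session = PhotometrySession(
        timestamps=t, signal_470=sig, control_415=ctl, rate=rate
    )
    return session, true_times


def shift_track(track: AnnotationTrack, start: float, duration: float) -> AnnotationTrack:
    """Re-express a track in window coordinates ``[0, duration)``.

    Bouts are clipped to ``[start, start + duration)`` and shifted so the
    window begins at 0 — used to compare ground truth against bouts scored
    in the extracted analysis window.  The span reflects the part of the
    window the track actually covers.
    """
    return track.window(start, duration)
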