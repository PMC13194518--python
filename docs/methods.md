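# Methods

## Signal model and segmentation

A tail-suspension load-cell recording is a calibrated force time series
(grams, nominally 80 Hz) with two regimes: a low standing level while the
animal is on the platform and a plateau near the animal's weight once it
hangs. Start detection is two-step:

1. **Provisional start.** The raw trace is smoothed with a zero-phase
   100-point moving average, implemented as edge-replicated padding followed
   by a forward and a backward pass of the causal box filter (equivalent to
   `scipy.signal.filtfilt` with `padtype="constant"`, `padlen=100`; the
   double pass cancels the box filter's group delay). The *period threshold*
   is `0.9·mean + 0.1·min` of the smoothed trace, and the provisional start
   is the earliest sample after which the smoothed signal stays **strictly**
   above that threshold for at least 270 s (`ceil(270·rate)` samples,
   closed-open). Strict inequality and the sample-count convention pin the
   boundary behavior deterministically.
2. **Refinement.** Within the post-start segment the baseline is the mean of
   the contiguous 800-sample window with the smallest population standard
   deviation (`÷n`; earliest window on ties) inside the middle third of the
   segment — read as one contiguous window, i.e. a physical quiescent
   plateau, rather than the union of the 800 individually least-variable
   samples, whose mean would mix disjoint epochs. The refined start is the
   first raw sample strictly above this baseline within ±30 s of the
   provisional start; the search is local because a global first-exceedance
   scan could latch onto pre-start noise. If no crossing exists the
   provisional start is kept and a warning logged.

The analysis window is the 360-s slice from the refined start,
baseline-subtracted and band-passed 1–20 Hz with a 4th-order Butterworth in
second-order sections, applied forward-backward (zero phase). Filter family
and order are configurable (`filter.band_hz`, `filter.order`).

Numerical note: the sliding-variance scan centers the segment before the
cumulative-sum recursion, keeping it faithful to a direct per-window
`std` to ~1e-13 relative; trace rates within 0.01% of the nominal rate are
snapped to it so that duration arithmetic (window length, bout sums) is
exact in floating point.

## Bout scoring

The band-passed signal oscillates around zero, so it is rectified into a
**movement envelope**: the rolling maximum of |x| over a centered 0.25-s
span (20 samples at 80 Hz; support `[i−n/2, i−n/2+n)`, clipped at edges).
A sample is *mobile* iff envelope > θ. This is the minimal rectification
consistent with comparing an oscillatory signal against a threshold in
grams; the span is configurable (`score.envelope_span_s`). No minimum bout
duration is imposed by default (`score.min_bout_s = 0`); when set, runs
shorter than the minimum are merged into their neighbors, shortest first,
earliest first among equals, with run lengths recomputed after every merge.

Outcome measures per subject: total immobility (immobile samples / rate),
latency (onset of the first immobile run; 360 s if none), cumulative
immobility at 1-s steps, and six per-minute immobility times. Total
mobility is defined as `360 − total immobility`, which makes time
conservation exact in floating point (summing both sides from per-bout
floats can miss by one ulp). Raising θ can only reclassify mobile samples
as immobile, so total immobility is non-decreasing in θ — the property
that gives the calibration objective its U shape.

## Threshold calibration

For each mouse, automated immobility time is evaluated at candidate
thresholds {0.4, 0.6, 0.8, 1.0, 1.2} g and paired with the manual reference
time (no rows deleted or imputed). A Random-Forest regressor
(`n_estimators=200`, seed 42, features `(θ, auto_time)`, target
`manual_time`) is trained on an animal-level 75/25 split (seeded
permutation of sorted subject ids; `round(0.75·n)` train animals) and
evaluated with grouped 5-fold cross-validation (no mouse spans folds),
mean absolute error averaged over folds. A randomized search (25 draws,
seed 42) over `n_estimators ∈ {100…600}`, `max_depth ∈ {None, 4…16}`,
`min_samples_leaf ∈ {1…8}`, `max_features ∈ {all, sqrt}` under the same
grouped CV is compared against the baseline; the baseline is kept unless
the tuned model strictly improves CV MAE. Test MAE is computed once on the
held-out animals.

The **global best threshold** is found by scanning θ over the candidate
range in 0.001-g steps (resolving three decimals). Per mouse, `auto_time(θ)`
is recomputed from the signal when the traces are available
(`auto_time_fn`), otherwise monotone piecewise-linear interpolation across
the candidate sweep. Two objectives are implemented:

- `direct` (default): minimize the mean over mice of
  `|auto_time(θ) − manual_time|`;
- `model`: minimize the mean over mice of
  `|forest-predicted manual − observed manual|`.

The direct objective is the default because, on cohorts scored at only five
candidate thresholds, each θ-region of the forest can learn to invert that
candidate's systematic bias, flattening the model objective to candidate
resolution and making its argmin unstable; the model route remains
available for cohorts with denser threshold sampling. Per-mouse argmin
thresholds ("individual optima") are reported alongside, and a warning is
raised if the global threshold falls outside their range. Ties resolve to
the smallest θ.

## Agreement metrics

Tracks at different native rates are resampled onto a common grid at the
finest native step; each grid point takes the state of the nearest native
sample (exact ties to the earlier sample), which keeps series strictly
binary. Tracks must cover the same span to within one native step and are
truncated to the overlap. With immobile as the positive class:
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R) (0 when
TP = 0), and Cohen's κ = (P₀−Pₑ)/(1−Pₑ) with Pₑ from the marginal class
frequencies; κ = 1 when observed agreement is perfect, including the
degenerate Pₑ = 1 case, and zero-denominator precision/recall map to 0 with
a logged warning (an all-mobile track, as under a strong antidepressant, is
data, not an error).

## Photometry

The isosbestic 415 nm channel is fit to the 470 nm channel by iteratively
reweighted least squares with Tukey bisquare weights (tuning constant
4.685, ≤ 50 iterations, tolerance 1e-8; statsmodels RLM), so calcium
transients are down-weighted and the fit captures shared drift and motion.
ΔF/F = (F − F_fit)/F_fit is z-scored over the whole session (no separate
baseline epoch is defined for this assay, and whole-session z-scoring makes
the unit self-calibrating). Transients are local maxima with topographic
prominence ≥ 0.5 SD; amplitude is reported as the z-score height at the
peak sample.

Bout-state summaries report, per bout, the trapezoidal z-score integral
divided by the integrated span (so a constant z yields exactly that
constant), peak frequency (count/duration) and mean peak amplitude, then
bout-wise means per state. Peri-onset alignment extracts ±1 s around every
bout transition at the photometry rate; pre-onset samples must lie inside
the immediately preceding bout and post-onset samples inside the current
bout (*event-pure*), everything else — including samples beyond the
recording edge — is masked and excluded from every average. Peri-onset
peak counts and amplitudes use event-pure peaks only, matching the masking
rule.

## Synthetic data generator

The generator is a pure function of its config and seed and emulates:

- a standing level (`standing_force_fraction × weight`, default 10% of a
  20–30 g animal) with Gaussian sensor noise SD 0.13 g (≈ ±0.4 g
  excursions);
- a linear 0.2-s rise to the suspended-weight plateau at the hang time
  (the truth start); tail lifting is fast but not instantaneous, and the
  rise bounds the attainable start-detection error;
- an alternating renewal bout schedule (exponential durations, mean
  immobile 10 s; mean mobile derived from the immobility-fraction target,
  default 0.55, a typical vehicle-treated level), starting mobile because
  suspended mice struggle first;
- struggle bursts as amplitude-modulated 2–10 Hz band-limited noise (inside
  the 1–20 Hz analysis band) during mobile bouts: full strength is 4 g
  (SD), and 20% of 0.5-s tiles are weak efforts at 5–35% of full strength.
  The weak fraction is what gives automated immobility time a genuine slope
  (~20 s/g) across the 0.4–1.2 g candidate band; without it every candidate
  threshold scores identically and no threshold calibration is
  identifiable;
- manual annotation as truth boundaries jittered by a truncated Gaussian
  (SD 0.1 s, capped at half the shorter adjacent bout so bouts never
  reorder) and snapped to the 30 fps frame grid;
- photometry at 40 Hz with a shared multiplicative drift (slow exponential
  × slow sine) on both channels, Gaussian sensor noise, and exponential
  transients (50 ms rise, 500 ms decay) added to the 470 channel only.
  Transient times are Poisson within bouts (0.4 Hz mobile, 0.05 Hz
  immobile, one extra at every mobility onset) thinned to a 1-s refractory
  so that recovery tests measure detector quality rather than transient
  overlap.

What passing tests on this generator do **not** show about real data:
struggle spectra, bout-duration distributions and observer error are
idealized (stationary band, exponential bouts, unbiased Gaussian jitter);
real recordings add slow drift, posture changes, cable artifacts and
systematic observer bias, so the shipped default threshold (0.792 g) and
any cohort-calibrated threshold remain hardware-dependent quantities to be
re-derived with `tstscore calibrate` on each rig.

## Problem sizes and reproducibility

Simulated sessions are 360-s windows plus margins at 80 Hz (~38k samples);
cohorts are 16 subjects, mirroring the assay's standard design. The
acceptance script scores 16 sessions end-to-end. Exhaustive-oracle tests
run on randomized inputs up to 50k samples. Every stochastic component
takes an explicit seed; identical inputs and seeds reproduce all outputs
byte-for-byte (log timestamps excluded).

## Known limitations

- Single-channel scoring only; no cross-talk correction between the four
  hardware channels and no drift correction beyond baseline subtraction.
- No graded mobility score from signal amplitude — states are binary.
- The rectification/envelope construction and the merging rule are declared
  conventions; the original acquisition software does not document its
  exact choices.
- Group-level inferential statistics (ANOVAs, post-hoc tests) are out of
  scope; the package emits the per-subject measures they would consume.
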