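# Methods

swallowkit analyses cervical-auscultation recordings of saliva swallows: a
dual-axis accelerometer (anterior-posterior, AP; superior-inferior, SI) and a
contact microphone (SOUND) sampled synchronously on the neck. The package
implements the full chain — synthetic data with ground truth, signal
conditioning, swallow detection, feature reduction, and a nonparametric
comparison battery — as a library with a thin CLI. This note records the
models, the parameters that matter, and the numerical choices made where the
design was genuinely open.

## Signal conditioning

**Device-noise inverse filtering.** The recording chain's baseline output is
modelled as an autoregressive process `x[t] = Σ a_i x[t−i] + e[t]`. The fit
is the modified-covariance (forward–backward) least-squares estimator: both
prediction directions are stacked into one least-squares system, which avoids
the windowing bias of autocorrelation-based fits. The order `p` is selected
over `0..max_order` (default 8 in the pipeline, 10 in the fitting API) by
minimising `BIC = N ln σ² + p ln N`. The fitted coefficients define the FIR
whitening filter `(1, −a_1, …, −a_p)` applied to task recordings. With an
order-0 model the filter is the identity.

**Spline detrending (accelerometer only).** Motion artefacts and other
low-frequency wander are captured by a least-squares spline of order 4
(cubic) on uniformly spaced knots, with `n_knots = round(N·f_l/fs)` (floor 2)
so the knot spacing equals one period of the corner frequency `f_l` — 3.77 Hz
for SI, 1.67 Hz for AP, values established for this sensor placement. The
baseline is subtracted; baseline + residual reconstructs the input exactly.
The sound channel is never detrended: its low-frequency content is retained
deliberately, because no lower band edge is established for swallowing
sounds.

**Wavelet denoising.** A discrete Meyer (`dmey`) decomposition to 10 levels
(automatically reduced when the record is too short for the 62-tap filter,
with a log notice). The noise scale is the robust estimate
`σ = median(|d₁|)/0.6745` from the finest detail level; every detail
coefficient is soft-thresholded at the universal threshold `σ√(2 ln N)`;
approximation coefficients are never shrunk. Boundary handling uses
periodization, which keeps the transform orthonormal so level energies
partition signal energy (within 1%, verified in tests).

*A consequence worth knowing:* swallow energy is concentrated at low
frequency, and coarse-scale Meyer atoms have effective support of seconds.
Denoising therefore annihilates broadband background noise (measured
suppression of >20 Hz background power: over four orders of magnitude) but
cannot erase low-frequency energy between swallows — both spline residual
below ~1 Hz on AP (whose corner is 1.67 Hz) and burst energy smeared through
the approximation band remain. The burst-to-background variance contrast
still improves on every channel, which is what detection relies on.

## Swallow detection

The detection signal is the sum of the squared unit-variance-normalised
accelerometer axes (either axis alone if only one is present), so neither
axis dominates. Features are the log of sliding-window variance — window
25 ms, hop 10 ms, both configurable; much shorter than the ~2 s swallow yet
long enough (≥ ~100 samples at 4 kHz) for a stable variance estimate.
Exactly-zero-variance windows clamp to a log-floor of −80.

Two-class fuzzy c-means (fuzzifier m = 2, tolerance 1e-6 on centroid shift,
max 300 iterations, random membership initialisation from a caller seed)
labels windows softly; the class with the higher centroid is "vibration".
Windows with vibration membership above 0.5 are active; each window is
identified with its centre sample, a run of active windows spans first
centre − window/2 to last centre + window/2, runs closer than 0.5 s merge,
and runs shorter than 0.3 s are dropped. The duration and gap thresholds
come from the physiological scale of a swallow (reported mean durations
around 1.8–2.2 s) and are configurable. The sound channel always inherits
the accelerometer segmentation, which makes transducer contrasts exactly
paired per swallow.

Nominal burst edges are soft — the synthesis envelope tails off into the
noise floor — so the detector is graded on mean absolute boundary error
(≤ 0.2 s on cohort runs) rather than per-edge error.

## Features

Eight features per channel per swallow, plus one shared duration:

* **Skewness, kurtosis** — standardised third and fourth central moments;
  kurtosis is non-excess (Gaussian → 3), the convention consistent with the
  magnitudes this battery reports (e.g. values near 12 for sounds).
* **Entropy-rate regularity** — the signal is normalised to zero mean/unit
  variance and quantised into 10 equal-width bins spanning its observed
  range (top edge inclusive). For pattern lengths L = 1..10, `SE(L)` is the
  Shannon entropy (nats) of overlapping L-grams; the corrected conditional
  entropy is `NCCE(L) = (SE(L) − SE(L−1) + perc(L)·SE(1)) / SE(1)` with
  `perc(L)` the fraction of L-grams occurring exactly once; the index is
  `1 − min_L NCCE(L)`, clipped to [0,1]. A constant signal maps to 1. For
  i.i.d. input the index does not reach 0 exactly: the plug-in entropy
  estimator under-counts by ~`m_L/(2N)` at the largest L whose patterns are
  still shared, leaving a floor of ≈0.02 for a 10-letter alphabet at any
  record length. Tests assert the random limit as ≤ 0.05 rather than
  pretending the estimator is unbiased; no bias correction is applied
  because the `perc` correction *is* this construction's bias handling.
* **Lempel-Ziv complexity** — the 100-level quantised sequence is parsed
  left-to-right into phrases, each the shortest prefix not previously
  produced as a phrase; with k phrases over n symbols the normalised value
  is `k·log₁₀₀(n)/n`. The implementation is verified against an independent
  brute-force parser on every sequence of length ≤ 12 over alphabets {2,3}.
* **Peak, centre frequency and bandwidth** — the magnitude spectrum on
  non-negative frequencies is treated as a mass distribution: centre is its
  mean, bandwidth its standard deviation (magnitude weighting, not power).
  The DC bin stays in the centroid/bandwidth sums but is excluded from the
  peak search by default (a residual offset should not masquerade as a
  spectral peak); both choices are configurable.
* **Wavelet entropy** — Shannon entropy, in nats, of the relative energy
  distribution over the 10-level discrete Meyer decomposition (approximation
  + details); natural log is the unit consistent with reported values of
  1.0–1.7 against 11 bins (max ln 11 ≈ 2.40). The per-level energies are
  also exposed for decomposition-profile plots.

Degenerate segment signals (constant or all-zero spans) yield NaN features
and a log notice rather than an error, so one bad segment cannot abort a
cohort run.

## Statistics

* **Transducer family:** 16 Wilcoxon signed-rank tests (8 features × {AP vs
  SOUND, SI vs SOUND}) on per-swallow paired differences. Duration is
  excluded — segmentation is shared, so it is identical by construction.
  Zero differences are discarded (Wilcoxon convention); all-zero difference
  vectors report p = 1. Exact p-values for ≤ 25 nonzero pairs, normal
  approximation with continuity correction above. Bonferroni threshold
  0.05/16, quoted to three decimals as 0.003.
* **Sex family:** 25 Wilcoxon rank-sum tests (8 features × 3 channels +
  duration) at 0.05/25 = 0.002. The default unit of analysis is the subject:
  swallows collapse to per-subject medians first, respecting independence;
  a pooled-swallow mode exists for sensitivity analysis.
* **Age:** ordinary least squares of each feature on age, stratified by sex,
  reporting slope, intercept and r². No significance is asserted for age
  effects — cohorts of this size lack the power to grade variance shares of
  a few percent, so the variance explained is reported as-is.

Type-I control of the corrected sex battery is verified by simulation: 200
null cohort feature tables (no sex structure, subject-level random effects
present) give a per-test rejection rate ≤ 0.01.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
swallowing biomechanics:

* **Device noise:** per-channel AR-coloured Gaussian noise (defaults:
  AR(2) (0.6, −0.2) on the accelerometers, AR(1) (0.4) on the microphone;
  innovation scale 0.02 against unit burst amplitude, i.e. a clean
  laboratory-grade recording). The AR model is exactly the process the
  conditioning chain fits and inverts.
* **Baseline wander (AP/SI only):** a sinusoid (0.1–0.4 Hz) plus a
  band-limited random walk, kept below ~0.5 Hz — the scale of respiration
  and slow neck motion, and within the removal band of the spline corners
  used downstream; total standard deviation 0.1.
* **Bursts:** random-phase surrogates of a two-lobe spectrum — a raised
  cosine on 0–20 Hz carrying `low_band_fraction` of the energy (defaults
  0.65 for the accelerometers, 0.55 for the microphone, reflecting that well
  over half of swallowing vibration and sound energy lies below 20 Hz) plus
  a Gaussian upper lobe placed by bisection so the magnitude-weighted
  centroid hits its target (defaults: AP 35 Hz, SI 40 Hz, SOUND 120 Hz).
  Deterministic bin magnitudes avoid the band-energy sampling scatter that
  white-noise colouring would leave on a 1–3 s record. An asymmetric
  envelope (peak position and rise/decay exponents driven by one skew
  parameter) emulates the slow-rise/fast-decay shape of anterior-posterior
  vibrations; burst durations are drawn from a clipped normal around 2 s,
  and consecutive swallows are separated by 1.5–3 s of background.
* **Cohort:** 55 subjects × 5 swallows by default (275 events), sexes
  assigned by largest-remainder rounding of the 28/55 male fraction, ages
  uniform on 18–65. Male bursts get a ×2 centroid and ×1.5 upper-lobe-width
  shift by default; setting `sex_effect` to identity gives null cohorts.
  Everything is bit-reproducible from `CohortSpec.seed`.

What the generator does **not** emulate: bolus-related variability, the
analog amplifier response, inter-swallow physiological events (coughs,
speech), electrode detachment, or any true biomechanical coupling between
the three channels (bursts share timing but are statistically independent
across channels). Passing pipeline tests on these cohorts therefore
demonstrates that the chain recovers what it assumes — clean, well-separated
bursts over stationary coloured noise — not that it is robust to every
artefact of clinical recordings.

## Problem sizes and runtime choices

Pipeline-scale runs use fs = 4 kHz rather than a full 40 kHz acquisition
rate; every spectral target in the generator sits far below either Nyquist,
and fs is a config knob. The cohort acceptance run is 55 subjects × ~25 s ×
3 channels at 4 kHz; AR noise baselines are 20 000 samples; statistical
calibration uses 200 replicates of table-level null cohorts (signal-level
synthesis would add nothing — the battery consumes only the feature table).
Oracle sweeps are exhaustive where cheap (all 8·10⁵ sequences of length ≤ 12
on alphabets {2,3} for the Lempel-Ziv parser) and simulation-based at
n = 10⁵–10⁶ elsewhere.

## Known limitations

* The entropy-rate index has the estimator floor described above; values
  from different alphabet sizes or pattern-length caps are not comparable.
* Fuzzy c-means on 1-D log-variance is near-deterministic for well-separated
  clusters but keeps a seed parameter; degenerate (constant-variance)
  recordings are rejected rather than force-clustered.
* The spline baseline is fit to the whole record, bursts included; with
  large bursts the fit acquires a small wiggle (~noise floor) in the gaps.
  Masked or iterative fitting would remove this at the cost of departing
  from the plain least-squares construction.
* WAV I/O maps channel names positionally; there is no provision for
  embedded channel metadata or proprietary acquisition formats.
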