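# swallowkit

Analysis of **cervical auscultation** signals — swallowing vibrations from a
dual-axis neck accelerometer (anterior-posterior and superior-inferior axes)
and swallowing sounds from a contact microphone — aimed at researchers
developing non-invasive screening for dysphagia. The package provides the
complete processing chain for saliva-swallow recordings as a tested Python
library: synthetic cohorts with ground truth, signal conditioning, automatic
swallow detection, per-swallow feature reduction, and the nonparametric
battery that compares features across transducers and demographics.

## What it computes

Each recording passes through three conditioning stages: an FIR whitening
filter `(1, −a₁, …, −a_p)` built from a modified-covariance AR fit of the
device's noise-only baseline (order by BIC); least-squares cubic-spline
detrending of the accelerometer axes with `round(N·f_l/fs)` knots
(f_l = 3.77 Hz for S-I, 1.67 Hz for A-P) — sounds keep their low
frequencies; and 10-level discrete Meyer wavelet denoising with soft
thresholding at the universal threshold `σ√(2 ln N)`,
`σ = median(|d₁|)/0.6745`. Swallows are detected by two-class fuzzy c-means
on log sliding-window variance of the fused accelerometer axes; the sound
channel inherits the detected time points, so transducer comparisons are
paired per swallow.

Every swallow × channel reduces to nine features:

| domain | features |
| --- | --- |
| time | skewness, kurtosis (non-excess), duration (shared across channels) |
| information | entropy-rate regularity `1 − min_L NCCE(L)` on a 10-level quantisation; normalised Lempel-Ziv complexity `k·log₁₀₀(n)/n` on a 100-level quantisation |
| frequency | peak frequency, magnitude-weighted spectral centroid, bandwidth (spectral standard deviation) |
| time-frequency | wavelet entropy `−Σ Er ln Er` over the 10-level Meyer energy distribution |

The statistical battery runs 16 Wilcoxon signed-rank transducer contrasts
(each feature, A-P vs sound and S-I vs sound; Bonferroni α = 0.05/16 ≈
0.003), 25 Wilcoxon rank-sum sex contrasts on per-subject medians
(α = 0.05/25 = 0.002), and per-sex least-squares regressions of every
feature on age, reporting variance explained.

Because no public recordings exist for this task, the `synth` module
generates tri-channel cohorts with known ground truth: AR-coloured device
noise, sub-Hz accelerometer baseline wander, and amplitude-modulated
band-shaped bursts carrying most of their energy below 20 Hz, with
configurable male/female spectral shifts — the structure the analysis
chain assumes, with every knob explicit. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

Condition a synthetic recording and detect its swallows
(`examples/02_condition_and_segment.py`):

```text
fitted AR(2) noise model for AP: coeffs (0.609, -0.2)
fitted AR(2) noise model for SI: coeffs (0.583, -0.185)
fitted AR(1) noise model for SOUND: coeffs (0.395,)

detected vs ground truth (seconds):
  [  1.30,   3.19)   truth [  1.28,   3.28)
  [  4.77,   6.86)   truth [  4.79,   6.94)
  [  9.68,  11.41)   truth [  9.67,  11.53)
  [ 14.21,  15.78)   truth [ 14.23,  15.78)
  [ 17.93,  19.71)   truth [ 17.98,  19.76)

recall 1.00, mean boundary error 46 ms
```

The fitted noise models recover the generator's AR coefficients, and all
five swallows are found with boundaries a few tens of milliseconds from
ground truth. Reducing one detected swallow to features
(`examples/03_swallow_features.py`) prints, per channel, the nine values —
e.g. a sound-channel centre frequency of ~258 Hz against ~74–91 Hz on the
accelerometer axes, the higher-frequency character that distinguishes
swallowing sounds from vibrations. `examples/04_compare_transducers_and_sexes.py`
runs the full battery on a 20-subject cohort and prints which contrasts
clear their corrected thresholds (the generator's injected ×2 male centroid
shift is detected on all three channels at p ≈ 1e-5).

The same stages are scriptable from the shell:

```bash
swallowkit run-all --config cohort.json --seed 1 --out results/
```

writes `features.csv`, `segments.json`, `tests.csv`, `regressions.csv`,
per-sex summary tables and a wavelet energy profile.

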