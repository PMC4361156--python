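"""Synthetic tri-channel swallow recordings with known ground truth.

The generator emulates the statistical structure of cervical-auscultation
recordings rather than the biomechanics of swallowing:

* **device noise** — each channel carries AR-coloured Gaussian noise, the
  inverse of the AR noise model that the conditioning chain later fits and
  removes;
* **baseline wander** — accelerometer channels additionally drift below 1 Hz
  (a sinusoid plus a band-limited random-walk component); the sound channel
  does not drift;
* **swallow bursts** — each swallow is amplitude-modulated Gaussian noise
  shaped by a two-component spectrum: a sub-20 Hz lobe carrying most of the
  energy (as real swallow vibrations and sounds do) and a tunable
  higher-frequency lobe placed so the magnitude-weighted spectral centroid
  hits a requested target.  An asymmetric envelope emulates the slow rise /
  fast decay of anterior-posterior vibrations.

A cohort mirrors the study design this pipeline targets: 55 subjects, five
saliva swallows each, sexes split 28/27, ages uniform on 18-65, with a
configurable multiplicative male shift on burst centroid and bandwidth.
Everything is reproducible bit-for-bit from ``CohortSpec.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ParameterError
from .io import FEATURE_TABLE_COLUMNS, MultiChannelRecording, SubjectMeta
from .segment import SwallowSegment

__all__ = [
    "BurstParams",
    "CohortSpec",
    "gen_device_noise",
    "gen_swallow_burst",
    "gen_recording",
    "gen_cohort",
    "gen_null_feature_table",
]

_LOW_BAND_HZ = 20.0  # upper edge of the dominant low-frequency lobe


@dataclass(frozen=True)
class BurstParams:
    """Spectral and temporal shape of one synthetic swallow burst.

    ``envelope_skew`` controls rise/decay asymmetry: negative values give a
    long, saturating rise followed by a fast decay (the envelope then spends
    most of its time near the peak, so its sample skewness is negative).
    ``high_lobe_width_hz`` sets the spread of the upper spectral lobe and is
    the handle through which sex effects widen the bandwidth; it defaults to
    35% of the centroid.
    """

    duration_s: float = 2.0
    amplitude: float = 1.0
    centroid_hz: float = 60.0
    low_band_fraction: float = 0.6
    envelope_skew: float = 0.0
    high_lobe_width_hz: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError(f"duration_s must be positive, got {self.duration_s}")
        if not 0.0 <= self.low_band_fraction <= 1.0:
            raise ParameterError(
                f"low_band_fraction must be in [0, 1], got {self.low_band_fraction}"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    Defaults follow the study design the pipeline is built for: 55 subjects
    with five saliva swallows each, a near-even sex split, ages 18-65, and a
    male shift of x2 on burst spectral centroid and x1.5 on the upper-lobe
    width.  Burst durations are drawn per swallow from a clipped normal
    around 2 s; consecutive swallows are separated by a few seconds of
    background.  The test-scale sampling rate is 4 kHz; ``fs`` is a knob.
    """

    n_subjects: int = 55
    swallows_per_subject: int = 5
    sex_ratio: float = 28 / 55  # fraction male
    age_range: tuple[float, float] = (18.0, 65.0)
    fs: float = 4000.0
    sex_effect: dict[str, float] = field(
        default_factory=lambda: {"centroid": 2.0, "bandwidth": 1.5}
    )
    burst_params: dict[str, BurstParams] = field(
        default_factory=lambda: {
            "AP": BurstParams(centroid_hz=35.0, low_band_fraction=0.65,
                              envelope_skew=-1.0),
            "SI": BurstParams(centroid_hz=40.0, low_band_fraction=0.65),
            "SOUND": BurstParams(centroid_hz=120.0, low_band_fraction=0.55),
        }
    )
    noise_ar_coeffs: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "AP": (0.6, -0.2),
            "SI": (0.6, -0.2),
            "SOUND": (0.4,),
        }
    )
    noise_scale: float = 0.02
    drift_amplitude: float = 0.1
    duration_mean_s: float = 2.0
    duration_sd_s: float = 0.5
    duration_clip_s: tuple[float, float] = (1.0, 3.5)
    gap_range_s: tuple[float, float] = (1.5, 3.0)
    amplitude_jitter_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0 or self.swallows_per_subject < 0:
            raise ParameterError("cohort sizes must be nonnegative")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ParameterError(f"sex_ratio must be in [0, 1], got {self.sex_ratio}")


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def gen_device_noise(
    ar_coeffs, n: int, scale: float = 1.0, seed: int = 0
) -> np.ndarray:
    """AR(p)-coloured Gaussian noise with innovation std ``scale``.

    ``ar_coeffs = (a_1, ..., a_p)`` defines ``x[t] = sum a_i x[t-i] + e[t]``;
    an empty coefficient vector yields white noise.  A burn-in of max(1000,
    10 p) samples is generated and discarded so the output is stationary.
    """
    a = np.asarray(ar_coeffs, dtype=float)
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if a.size:
        poly = np.concatenate(([1.0], -a))
        if np.any(np.abs(np.roots(poly)) >= 1.0):
            raise ParameterError(f"AR coefficients {list(a)} are unstable")
    rng = np.random.default_rng(seed)
    burn = max(1000, 10 * a.size)
    e = rng.normal(0.0, scale, size=n + burn)
    if a.size == 0:
        return e[burn:]
    x = sps.lfilter([1.0], np.concatenate(([1.0], -a)), e)
    return x[burn:]


def ar_psd(ar_coeffs, freqs: np.ndarray, fs: float, scale: float = 1.0) -> np.ndarray:
    """Closed-form power spectral density of the AR noise model.

    One-sided density: ``2 * scale^2 / (fs * |1 - sum a_k e^{-i 2 pi f k / fs}|^2)``.
    Useful as an analytic reference when checking generated noise spectra.
    """
    a = np.asarray(ar_coeffs, dtype=float)
    w = 2.0 * np.pi * np.asarray(freqs) / fs
    denom = np.ones_like(w, dtype=complex)
    for k, ak in enumerate(a, start=1):
        denom = denom - ak * np.exp(-1j * k * w)
    return 2.0 * scale**2 / (fs * np.abs(denom) ** 2)


# ---------------------------------------------------------------------------
# bursts
# ---------------------------------------------------------------------------

def _burst_psd_shape(
    freqs: np.ndarray, f_hi: float, width: float, low_frac: float
) -> np.ndarray:
    """Two-lobe PSD: raised-cosine lobe on [0, 20 Hz] + Gaussian upper lobe."""
    lo = np.where(
        freqs <= _LOW_BAND_HZ,
        np.cos(np.pi * freqs / (2.0 * _LOW_BAND_HZ)) ** 2,
        0.0,
    )
    hi = np.exp(-0.5 * ((freqs - f_hi) / width) ** 2)
    lo_sum = lo.sum()
    hi_sum = hi.sum()
    shape = np.zeros_like(freqs)
    if lo_sum > 0:
        shape += low_frac * lo / lo_sum
    if hi_sum > 0:
        shape += (1.0 - low_frac) * hi / hi_sum
    return shape


def _magnitude_centroid(freqs: np.ndarray, psd: np.ndarray) -> float:
    mag = np.sqrt(psd)
    return float((freqs * mag).sum() / mag.sum())


def _solve_high_lobe(
    freqs: np.ndarray, target: float, width: float, low_frac: float
) -> float:
    """Place the upper lobe so the magnitude-weighted centroid hits ``target``."""
    f_lo, f_hi = _LOW_BAND_HZ, float(freqs[-1]) * 0.95
    c_min = _magnitude_centroid(freqs, _burst_psd_shape(freqs, f_lo, width, low_frac))
    c_max = _magnitude_centroid(freqs, _burst_psd_shape(freqs, f_hi, width, low_frac))
    if target <= c_min:
        return f_lo
    if target >= c_max:
        return f_hi
    for _ in range(60):
        mid = 0.5 * (f_lo + f_hi)
        c = _magnitude_centroid(freqs, _burst_psd_shape(freqs, mid, width, low_frac))
        if c < target:
            f_lo = mid
        else:
            f_hi = mid
    return 0.5 * (f_lo + f_hi)


def burst_envelope(n: int, skew: float) -> np.ndarray:
    """Asymmetric unit-peak envelope over ``n`` samples.

    The peak sits at fraction ``p = 1 / (1 + exp(skew))`` of the duration, so
    negative skew puts it late (slow rise, fast decay).  The rise follows
    ``u^exp(skew)`` (concave for negative skew: the envelope saturates near
    the peak early) and the decay ``u^exp(-skew)``.
    """
    if n < 1:
        raise ParameterError("envelope needs at least one sample")
    p = 1.0 / (1.0 + math.exp(skew))
    t = np.linspace(0.0, 1.0, n)
    peak = max(min(p, 1.0 - 1.0 / max(n, 2)), 1.0 / max(n, 2))
    rise_exp = math.exp(skew)
    fall_exp = math.exp(-skew)
    env = np.empty(n)
    rising = t <= peak
    env[rising] = (t[rising] / peak) ** rise_exp
    env[~rising] = ((1.0 - t[~rising]) / (1.0 - peak)) ** fall_exp
    return env


def gen_swallow_burst(
    params: BurstParams, fs: float, seed: int = 0
) -> np.ndarray:
    """Generate one amplitude-modulated band-shaped noise burst.

    The burst is a random-phase surrogate of the two-lobe spectrum: bin
    magnitudes follow the target spectral shape exactly while phases are
    i.i.d. uniform, which gives Gaussian-like noise whose band energy split
    and magnitude-weighted centroid match ``low_band_fraction`` and
    ``centroid_hz`` without the large sampling scatter that white-noise
    colouring would leave on a 1-3 s record.  The result is normalised to
    unit RMS, multiplied by the asymmetric envelope and by
    ``params.amplitude``.
    """
    if params.centroid_hz >= fs / 2:
        raise ParameterError(
            f"centroid {params.centroid_hz} Hz is not below Nyquist ({fs / 2} Hz)"
        )
    n = int(round(params.duration_s * fs))
    if params.amplitude == 0.0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    width = params.high_lobe_width_hz or max(10.0, 0.35 * params.centroid_hz)
    f_hi = _solve_high_lobe(
        freqs, params.centroid_hz, width, params.low_band_fraction
    )
    shape = _burst_psd_shape(freqs, f_hi, width, params.low_band_fraction)
    phases = np.exp(2j * np.pi * rng.uniform(size=len(freqs)))
    phases[0] = 1.0  # DC stays real
    if n % 2 == 0:
        phases[-1] = 1.0  # Nyquist bin likewise
    x = np.fft.irfft(np.sqrt(shape) * phases, n)
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x /= rms
    env = burst_envelope(n, params.envelope_skew)
    return params.amplitude * env * x


# ---------------------------------------------------------------------------
# recordings and cohorts
# ---------------------------------------------------------------------------

def _baseline_wander(n: int, fs: float, amplitude: float, rng) -> np.ndarray:
    """Sub-1 Hz drift: sinusoid + band-limited random walk, std = amplitude.

    The mixture is kept below ~0.5 Hz, the scale of respiration and slow neck
    motion, and within the removal band of the spline detrending corner
    frequencies used downstream.
    """
    if amplitude == 0.0 or n < 2:
        return np.zeros(n)
    t = np.arange(n) / fs
    f0 = rng.uniform(0.1, 0.4)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    sine = np.sin(2.0 * np.pi * f0 * t + phase)
    walk = np.cumsum(rng.standard_normal(n))
    sos = sps.butter(4, 0.5, btype="low", fs=fs, output="sos")
    walk = sps.sosfiltfilt(sos, walk)
    walk = walk - walk.mean()
    sd = walk.std()
    if sd > 0:
        walk = walk / sd
    drift = sine + walk
    return amplitude * drift / np.sqrt(2.0)


def _male_params(p: BurstParams, sex_effect: dict[str, float]) -> BurstParams:
    centroid = p.centroid_hz * sex_effect.get("centroid", 1.0)
    width = p.high_lobe_width_hz or max(10.0, 0.35 * p.centroid_hz)
    width *= sex_effect.get("bandwidth", 1.0)
    return replace(p, centroid_hz=centroid, high_lobe_width_hz=width)


def gen_recording(
    spec: CohortSpec, subject: SubjectMeta, seed: int = 0
) -> tuple[MultiChannelRecording, list[SwallowSegment]]:
    """Generate one subject's recording plus ground-truth swallow segments.

    The layout is lead-in, then ``swallows_per_subject`` bursts separated by
    gaps drawn from ``gap_range_s`` (always >= 1 s), then a tail.  All three
    channels place bursts at identical sample positions; AP/SI additionally
    carry baseline wander.  Male subjects use burst parameters shifted by
    ``spec.sex_effect``.
    """
    rng = np.random.default_rng(seed)
    fs = spec.fs
    k = spec.swallows_per_subject

    durations = np.clip(
        rng.normal(spec.duration_mean_s, spec.duration_sd_s, size=k),
        *spec.duration_clip_s,
    )
    gaps = rng.uniform(*spec.gap_range_s, size=k + 1)
    gaps[0] = rng.uniform(1.0, 2.0)  # lead-in
    gaps[-1] = rng.uniform(1.0, 2.0)  # tail
    if k == 0:
        total_s = 10.0
    else:
        total_s = float(gaps.sum() + durations.sum())
    n = int(round(total_s * fs))

    # burst positions, shared by all channels
    positions: list[tuple[int, int]] = []
    pos = gaps[0]
    for d, g in zip(durations, gaps[1:]):
        i0 = int(round(pos * fs))
        i1 = min(i0 + int(round(d * fs)), n)
        positions.append((i0, i1))
        pos += d + g

    channels: dict[str, np.ndarray] = {}
    for name in ("AP", "SI", "SOUND"):
        noise_seed = int(rng.integers(2**31))
        x = gen_device_noise(
            spec.noise_ar_coeffs.get(name, ()), n, spec.noise_scale, noise_seed
        )
        if name in ("AP", "SI"):
            x = x + _baseline_wander(n, fs, spec.drift_amplitude, rng)
        params = spec.burst_params[name]
        if subject.sex == "male":
            params = _male_params(params, spec.sex_effect)
        for (i0, i1), d in zip(positions, durations):
            amp = params.amplitude * math.exp(
                rng.normal(0.0, spec.amplitude_jitter_sd)
            )
            burst = gen_swallow_burst(
                replace(params, duration_s=float(d), amplitude=amp),
                fs,
                seed=int(rng.integers(2**31)),
            )
            x[i0:i1] += burst[: i1 - i0]
        channels[name] = x

    segments = [SwallowSegment.from_samples(i0, i1, fs) for i0, i1 in positions]

    rec = MultiChannelRecording(fs=fs, channels=channels, subject=subject)
    return rec, segments


def assign_sexes(n_subjects: int, sex_ratio: float) -> list[str]:
    """Largest-remainder assignment of sexes matching ``sex_ratio`` males."""
    exact_m = n_subjects * sex_ratio
    n_m = int(math.floor(exact_m))
    n_f = int(math.floor(n_subjects - exact_m))
    leftovers = n_subjects - n_m - n_f
    if leftovers:
        rem_m = exact_m - n_m
        rem_f = (n_subjects - exact_m) - n_f
        if rem_m >= rem_f:
            n_m += leftovers
        else:
            n_f += leftovers
    return ["male"] * n_m + ["female"] * n_f


def gen_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[MultiChannelRecording, list[SwallowSegment]]], pd.DataFrame]:
    """Generate a full cohort of recordings with ground truth.

    Returns the list of (recording, segments) pairs and a metadata table
    (subject_id, sex, age) ready to join onto a feature table.  Sexes follow
    ``sex_ratio`` by largest-remainder rounding; ages are uniform on
    ``age_range``.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sexes = assign_sexes(spec.n_subjects, spec.sex_ratio)
    ages = rng.uniform(*spec.age_range, size=spec.n_subjects)
    out = []
    meta_rows = []
    for i in range(spec.n_subjects):
        subject = SubjectMeta(
            subject_id=f"S{i:03d}", sex=sexes[i], age=float(ages[i])
        )
        sub_seed = int(rng.integers(2**31))
        out.append(gen_recording(spec, subject, seed=sub_seed))
        meta_rows.append(
            {"subject_id": subject.subject_id, "sex": subject.sex, "age": subject.age}
        )
    meta = pd.DataFrame(meta_rows, columns=["subject_id", "sex", "age"])
    return out, meta


# ---------------------------------------------------------------------------
# fast null cohorts for statistical calibration
# ---------------------------------------------------------------------------

#: plausible per-feature (location, scale) used by the null table sampler
_NULL_FEATURE_DISTS = {
    "skewness": (0.0, 1.0),
    "kurtosis": (10.0, 5.0),
    "entropy_rate": (0.98, 0.01),
    "lz_complexity": (0.07, 0.02),
    "peak_freq_hz": (10.0, 5.0),
    "centre_freq_hz": (60.0, 30.0),
    "bandwidth_hz": (100.0, 40.0),
    "wavelet_entropy": (1.4, 0.5),
}


def gen_null_feature_table(
    n_subjects: int = 55,
    swallows_per_subject: int = 5,
    sex_ratio: float = 28 / 55,
    seed: int = 0,
    subject_sd_frac: float = 0.5,
) -> pd.DataFrame:
    """Sample a cohort feature table with no sex-dependent structure.

    Feature values are drawn directly (no signal synthesis) with a
    subject-level random effect plus per-swallow noise, identically for both
    sexes, which makes large replicate counts affordable for type-I-error
    calibration of the statistical battery.  Ages are uniform on 18-65.
    """
    rng = np.random.default_rng(seed)
    sexes = assign_sexes(n_subjects, sex_ratio)
    rows = []
    for i in range(n_subjects):
        sid = f"S{i:03d}"
        age = float(rng.uniform(18.0, 65.0))
        subj_z = rng.standard_normal(len(_NULL_FEATURE_DISTS) + 1)
        for sw in range(swallows_per_subject):
            dur = 2.0 + 0.4 * subj_z[-1] + 0.3 * rng.standard_normal()
            rows.append(
                {
                    "subject_id": sid, "sex": sexes[i], "age": age,
                    "swallow_idx": sw, "channel": "ALL",
                    "feature": "duration_s", "value": max(dur, 0.2),
                }
            )
            for channel in ("AP", "SI", "SOUND"):
                for j, (feat, (loc, scale)) in enumerate(
                    _NULL_FEATURE_DISTS.items()
                ):
                    value = (
                        loc
                        + scale * subject_sd_frac * subj_z[j]
                        + scale * rng.standard_normal()
                    )
                    rows.append(
                        {
                            "subject_id": sid, "sex": sexes[i], "age": age,
                            "swallow_idx": sw, "channel": channel,
                            "feature": feat, "value": value,
                        }
                    )
    return pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))
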