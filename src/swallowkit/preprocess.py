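"""Signal conditioning for swallowing vibration and sound recordings.

The chain mirrors how cervical-auscultation data are conditioned in practice:

1. **Device-noise inverse filtering.**  The recording chain's baseline output
   (sensor attached, no swallowing) is modelled as an autoregressive process
   fitted by the modified-covariance method, with the order chosen by BIC.
   The fitted coefficients define an FIR whitening filter
   ``(1, -a_1, ..., -a_p)`` that is applied to the task recordings.
2. **Spline detrending** (accelerometer channels only).  Head and neck motion
   produces low-frequency baseline wander; a least-squares spline with knot
   spacing of one period of a channel-specific corner frequency ``f_l``
   (SI: 3.77 Hz, AP: 1.67 Hz) captures the wander, which is subtracted.
   Sound channels are left untouched at low frequency.
3. **Wavelet denoising.**  A 10-level discrete Meyer decomposition with soft
   thresholding at the universal threshold sigma*sqrt(2 ln N), sigma estimated
   robustly from the finest-scale detail coefficients as median(|d1|)/0.6745.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import LSQUnivariateSpline

from .errors import ConfigurationError, DegenerateSignalError, ParameterError
from .io import MultiChannelRecording

logger = logging.getLogger(__name__)

__all__ = [
    "ARModel",
    "SplineConfig",
    "DenoiseConfig",
    "PreprocessConfig",
    "fit_ar_noise_model",
    "inverse_filter",
    "spline_baseline",
    "estimate_noise_sigma",
    "wavelet_denoise",
    "preprocess_recording",
    "ar_models_to_json",
    "ar_models_from_json",
]


# ---------------------------------------------------------------------------
# autoregressive device-noise model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ARModel:
    """Autoregressive model x[t] = sum_i a_i x[t-i] + e[t], e ~ N(0, noise_var)."""

    coeffs: tuple[float, ...]
    noise_var: float
    bic: float = math.nan

    @property
    def order(self) -> int:
        return len(self.coeffs)

    def is_stable(self) -> bool:
        """True when all poles of 1/(1 - sum a_i z^-i) lie inside the unit circle."""
        if self.order == 0:
            return True
        poly = np.concatenate(([1.0], -np.asarray(self.coeffs)))
        return bool(np.all(np.abs(np.roots(poly)) < 1.0))


def _modified_covariance_fit(x: np.ndarray, p: int) -> tuple[np.ndarray, float]:
    """Least-squares AR(p) fit minimising forward+backward prediction error.

    Forward rows predict x[t] from x[t-1..t-p]; backward rows predict x[t]
    from x[t+1..t+p].  Stacking both halves is the modified-covariance
    (forward-backward) estimator; no windowing of the data is applied.
    """
    n = len(x)
    if p == 0:
        return np.empty(0), float(np.mean(x**2))
    # forward design matrix: row t has x[t-1], ..., x[t-p]
    idx = np.arange(p, n)[:, None] - np.arange(1, p + 1)[None, :]
    fwd = x[idx]
    fwd_y = x[p:]
    # backward design matrix: row t has x[t+1], ..., x[t+p]
    idxb = np.arange(0, n - p)[:, None] + np.arange(1, p + 1)[None, :]
    bwd = x[idxb]
    bwd_y = x[: n - p]
    design = np.vstack([fwd, bwd])
    target = np.concatenate([fwd_y, bwd_y])
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coeffs
    noise_var = float(np.mean(resid**2))
    return coeffs, noise_var


def fit_ar_noise_model(baseline: np.ndarray, max_order: int = 10) -> ARModel:
    """Fit an AR device-noise model, selecting the order by BIC.

    For each candidate order ``p`` in ``0..max_order`` a modified-covariance
    fit is computed and scored with ``BIC = N ln(noise_var) + p ln(N)``; the
    minimiser is returned.

    Parameters
    ----------
    baseline
        Noise-only recording of the device (no swallowing activity).
    max_order
        Largest order considered.  Must be well below the record length.
    """
    x = np.asarray(baseline, dtype=float)
    n = len(x)
    if max_order < 0:
        raise ParameterError(f"max_order must be >= 0, got {max_order}")
    if n == 0 or np.ptp(x) == 0:
        raise DegenerateSignalError("baseline has zero variance; cannot fit AR model")
    if max_order >= n / 3:
        raise ParameterError(
            f"max_order={max_order} too large for baseline of length {n}"
        )
    x = x - x.mean()

    best: ARModel | None = None
    for p in range(max_order + 1):
        coeffs, noise_var = _modified_covariance_fit(x, p)
        noise_var = max(noise_var, np.finfo(float).tiny)
        bic = n * math.log(noise_var) + p * math.log(n)
        if best is None or bic < best.bic:
            best = ARModel(
                coeffs=tuple(float(c) for c in coeffs),
                noise_var=noise_var,
                bic=bic,
            )
    assert best is not None
    return best


def inverse_filter(x: np.ndarray, model: ARModel) -> np.ndarray:
    """Whiten ``x`` with the FIR filter (1, -a_1, ..., -a_p).

    Output has the input length; initial conditions are zero, so an order-0
    model returns the input unchanged.
    """
    x = np.asarray(x, dtype=float)
    if model.order == 0:
        return x.copy()
    taps = np.concatenate(([1.0], -np.asarray(model.coeffs)))
    return sps.lfilter(taps, [1.0], x)


def ar_models_to_json(models: dict[str, ARModel]) -> dict:
    """Serialise per-channel AR models to a JSON-ready dict."""
    return {
        ch: {
            "coeffs": list(m.coeffs),
            "noise_var": m.noise_var,
            "order": m.order,
        }
        for ch, m in models.items()
    }


def ar_models_from_json(payload: dict) -> dict[str, ARModel]:
    """Inverse of :func:`ar_models_to_json`."""
    return {
        ch: ARModel(coeffs=tuple(d["coeffs"]), noise_var=float(d["noise_var"]))
        for ch, d in payload.items()
    }


# ---------------------------------------------------------------------------
# spline baseline removal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplineConfig:
    """Least-squares spline detrending configuration.

    ``f_l`` is the corner frequency whose period sets the knot spacing:
    ``n_knots = round(N * f_l / fs)`` with a floor of 2, so slower channels
    get fewer knots and the baseline cannot follow the swallow itself.
    """

    spline_order: int = 4  # polynomial order; degree = order - 1
    f_l_hz: dict[str, float] = field(
        default_factory=lambda: {"SI": 3.77, "AP": 1.67}
    )

    def n_knots(self, n_samples: int, fs: float, channel: str = "AP") -> int:
        f_l = self.f_l_hz[channel] if channel in self.f_l_hz else min(
            self.f_l_hz.values()
        )
        if f_l >= fs / 2:
            raise ParameterError(f"f_l={f_l} must be below Nyquist ({fs / 2})")
        return max(2, int(round(n_samples * f_l / fs)))


def spline_baseline(
    x: np.ndarray, fs: float, cfg: SplineConfig | None = None, channel: str = "AP"
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a least-squares spline baseline and return (baseline, detrended).

    Knots are uniformly spaced; the spline degree is ``spline_order - 1``
    (fourth-order = cubic).  ``detrended = x - baseline`` reconstructs the
    input exactly by construction.
    """
    cfg = cfg or SplineConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    n_knots = cfg.n_knots(n, fs, channel)
    degree = cfg.spline_order - 1
    if n < n_knots * cfg.spline_order:
        raise ParameterError(
            f"signal of length {n} too short for {n_knots} knots of order "
            f"{cfg.spline_order}"
        )
    t = np.arange(n, dtype=float)
    # n_knots uniform knots across the span; endpoints are implicit in the
    # spline basis, so pass the interior ones to the least-squares fitter.
    knots = np.linspace(0, n - 1, n_knots)[1:-1]
    if len(knots) == 0:
        coeffs = np.polyfit(t, x, degree)
        baseline = np.polyval(coeffs, t)
    else:
        spline = LSQUnivariateSpline(t, x, knots, k=degree)
        baseline = spline(t)
    return baseline, x - baseline


# ---------------------------------------------------------------------------
# wavelet denoising
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DenoiseConfig:
    """Discrete Meyer wavelet shrinkage configuration (universal threshold)."""

    wavelet: str = "dmey"
    levels: int = 10
    mode: str = "soft"
    dwt_mode: str = "periodization"


def estimate_noise_sigma(detail_coeffs: np.ndarray) -> float:
    """Robust noise scale: median(|coeffs|) / 0.6745.

    0.6745 is the median of |N(0,1)|, so for Gaussian noise the estimate is
    consistent for the true standard deviation while ignoring sparse signal
    coefficients.
    """
    c = np.asarray(detail_coeffs, dtype=float)
    if c.size == 0:
        raise DegenerateSignalError("cannot estimate sigma from empty coefficients")
    return float(np.median(np.abs(c)) / 0.6745)


def wavelet_denoise(x: np.ndarray, cfg: DenoiseConfig | None = None) -> np.ndarray:
    """Soft-threshold wavelet denoising at the universal threshold.

    The signal is decomposed to ``cfg.levels`` levels (automatically reduced
    when the record is too short, with a log notice), sigma is estimated from
    the finest detail level, and every detail coefficient is soft-thresholded
    at ``sigma * sqrt(2 ln N)`` before reconstruction at the input length.
    """
    cfg = cfg or DenoiseConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        raise DegenerateSignalError("cannot denoise an empty signal")
    wavelet = pywt.Wavelet(cfg.wavelet)
    max_level = pywt.dwt_max_level(n, wavelet.dec_len)
    levels = min(cfg.levels, max_level)
    if levels < 1:
        # record shorter than one filter length: nothing to shrink safely
        logger.info("signal of length %d too short for any DWT level", n)
        return x.copy()
    if levels < cfg.levels:
        logger.info(
            "reducing wavelet levels from %d to %d for signal of length %d",
            cfg.levels, levels, n,
        )
    coeffs = pywt.wavedec(x, wavelet, level=levels, mode=cfg.dwt_mode)
    finest = coeffs[-1]
    sigma = estimate_noise_sigma(finest)
    threshold = sigma * math.sqrt(2.0 * math.log(n)) if n > 1 else 0.0
    if threshold > 0.0:
        shrunk = [coeffs[0]] + [
            pywt.threshold(c, threshold, mode=cfg.mode) for c in coeffs[1:]
        ]
    else:
        shrunk = coeffs
    out = pywt.waverec(shrunk, wavelet, mode=cfg.dwt_mode)
    return out[:n]


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessConfig:
    """Bundle of the three conditioning stages."""

    spline: SplineConfig = field(default_factory=SplineConfig)
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)


def preprocess_recording(
    rec: MultiChannelRecording,
    ar_models: dict[str, ARModel],
    cfg: PreprocessConfig | None = None,
) -> MultiChannelRecording:
    """Condition every channel of a recording.

    Accelerometer channels (AP, SI) go through inverse filtering, spline
    detrending with their channel-specific corner frequency, then wavelet
    denoising.  The sound channel skips the spline stage: its low-frequency
    content is retained.
    """
    cfg = cfg or PreprocessConfig()
    out: dict[str, np.ndarray] = {}
    for name, x in rec.channels.items():
        if name not in ar_models:
            raise ConfigurationError(f"no AR noise model supplied for channel {name!r}")
        y = inverse_filter(x, ar_models[name])
        if name in ("AP", "SI"):
            _, y = spline_baseline(y, rec.fs, cfg.spline, channel=name)
        out[name] = wavelet_denoise(y, cfg.denoise)
    return rec.with_channels(out)
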