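"""Per-swallow signal features in the time, frequency and time-frequency domains.

Nine features describe each segmented swallow on each channel:

* time domain — skewness, (non-excess) kurtosis, and the swallow duration
  (shared across channels, since all transducers see the same event);
* information-theoretic — the entropy-rate regularity index on a 10-level
  quantisation and the normalised Lempel-Ziv complexity on a 100-level
  quantisation;
* frequency domain — peak frequency, spectral centroid (centre frequency)
  and bandwidth of the magnitude spectrum;
* time-frequency — the Shannon entropy of the relative energy distribution
  across a 10-level discrete Meyer wavelet decomposition (plus the per-level
  energies themselves for energy-profile plots).

The entropy-rate index uses the corrected conditional entropy: the raw
conditional entropy of L-gram patterns shrinks spuriously as patterns become
unique in a finite record, so the fraction of singleton patterns times the
first-order entropy is added back before normalising by the first-order
entropy.  One minus the minimum over pattern lengths maps a fully regular
signal to 1 and an i.i.d. one to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import stats as spstats

from .errors import DegenerateSignalError, ParameterError
from .io import FEATURE_TABLE_COLUMNS, MultiChannelRecording
from .segment import SwallowSegment

logger = logging.getLogger(__name__)

__all__ = [
    "QuantizedSequence",
    "SpectralSummary",
    "FeatureConfig",
    "PER_CHANNEL_FEATURES",
    "time_moments",
    "quantize",
    "shannon_entropy",
    "entropy_rate",
    "lz_complexity",
    "spectral_features",
    "wavelet_features",
    "extract_features",
]

#: The eight features computed per channel (duration is per swallow).
PER_CHANNEL_FEATURES = (
    "skewness",
    "kurtosis",
    "entropy_rate",
    "lz_complexity",
    "peak_freq_hz",
    "centre_freq_hz",
    "bandwidth_hz",
    "wavelet_entropy",
)


@dataclass(frozen=True)
class QuantizedSequence:
    """Integer symbol sequence from equal-width amplitude quantisation."""

    symbols: np.ndarray
    levels: int

    @property
    def source_n(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class SpectralSummary:
    """Positive-frequency magnitude spectrum of one swallow."""

    freqs: np.ndarray
    magnitudes: np.ndarray


@dataclass(frozen=True)
class FeatureConfig:
    """Knobs for the feature extractors."""

    entropy_levels: int = 10
    lz_levels: int = 100
    max_pattern_len: int = 10
    wavelet_levels: int = 10
    wavelet: str = "dmey"
    exclude_dc_peak: bool = True


# ---------------------------------------------------------------------------
# time domain
# ---------------------------------------------------------------------------

def time_moments(x: np.ndarray) -> tuple[float, float]:
    """Sample skewness and non-excess kurtosis (Gaussian -> 3)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ParameterError("need at least 3 samples for moments")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("zero-variance signal has undefined moments")
    skew = float(spstats.skew(x, bias=True))
    kurt = float(spstats.kurtosis(x, fisher=False, bias=True))
    return skew, kurt


# ---------------------------------------------------------------------------
# quantisation and information-theoretic features
# ---------------------------------------------------------------------------

def quantize(x: np.ndarray, levels: int) -> QuantizedSequence:
    """Normalise to zero mean / unit variance, then equal-width quantise.

    The [min, max] range of the normalised signal is split into ``levels``
    equal-width bins covering all observed values; the top edge is inclusive
    so the maximum maps to ``levels - 1``.
    """
    if levels < 2:
        raise ParameterError(f"levels must be >= 2, got {levels}")
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or len(x) == 0:
        raise DegenerateSignalError("constant signal cannot be quantised")
    z = (x - x.mean()) / sd
    lo, hi = z.min(), z.max()
    sym = np.floor((z - lo) / (hi - lo) * levels).astype(np.int64)
    np.clip(sym, 0, levels - 1, out=sym)
    return QuantizedSequence(symbols=sym, levels=levels)


def shannon_entropy(symbols: np.ndarray) -> float:
    """Shannon entropy in nats of the empirical symbol distribution."""
    symbols = np.asarray(symbols)
    if symbols.size == 0:
        raise ParameterError("empty symbol sequence")
    _, counts = np.unique(symbols, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log(p)))


def _gram_codes(sym: np.ndarray, L: int, levels: int) -> np.ndarray:
    """Encode all overlapping L-grams as integers (base ``levels``)."""
    n = len(sym) - L + 1
    codes = np.zeros(n, dtype=np.int64)
    for i in range(L):
        codes = codes * levels + sym[i : i + n]
    return codes


def entropy_rate(seq: QuantizedSequence, max_pattern_len: int = 10) -> float:
    """Regularity index from the corrected conditional entropy, in [0, 1].

    For pattern lengths ``L = 1..max_pattern_len`` the Shannon entropy
    ``SE(L)`` of overlapping L-grams gives the conditional entropy
    ``CE(L) = SE(L) - SE(L-1)`` (``SE(0) = 0``).  The corrected, normalised
    value ``NCCE(L) = (CE(L) + perc(L) * SE(1)) / SE(1)`` adds back the bias
    from the fraction ``perc(L)`` of L-grams occurring exactly once.  The
    index ``1 - min_L NCCE(L)`` is 1 for a constant signal and near 0 for an
    i.i.d. one.
    """
    sym = np.asarray(seq.symbols)
    if max_pattern_len < 1:
        raise ParameterError("max_pattern_len must be >= 1")
    if len(sym) < max_pattern_len + 1:
        raise ParameterError(
            f"sequence of length {len(sym)} shorter than max_pattern_len + 1"
        )
    # overflow guard: codes must fit an int64
    if max_pattern_len * math.log(seq.levels) >= 63 * math.log(2):
        raise ParameterError("levels**max_pattern_len exceeds int64 range")
    se1 = shannon_entropy(sym)
    if se1 == 0.0:  # constant sequence: perfectly regular by convention
        return 1.0
    best = math.inf
    prev_se = 0.0
    for L in range(1, max_pattern_len + 1):
        codes = _gram_codes(sym, L, seq.levels)
        _, counts = np.unique(codes, return_counts=True)
        p = counts / counts.sum()
        se = float(-np.sum(p * np.log(p)))
        ce = se - prev_se
        perc = float(np.count_nonzero(counts == 1) / counts.sum())
        ncce = (ce + perc * se1) / se1
        best = min(best, ncce)
        prev_se = se
    return float(min(1.0, max(0.0, 1.0 - best)))


def lz_complexity(seq: QuantizedSequence) -> float:
    """Normalised Lempel-Ziv complexity of a quantised sequence.

    The sequence is parsed left to right into phrases, each the shortest
    prefix of the remaining input not previously produced as a phrase; with
    ``k`` phrases over an ``n``-symbol sequence on an ``a``-letter alphabet
    the normalised complexity is ``k * log_a(n) / n``.
    """
    sym = np.asarray(seq.symbols).tolist()
    n = len(sym)
    if n == 0:
        raise ParameterError("empty sequence")
    phrases: set[tuple] = set()
    k = 0
    i = 0
    while i < n:
        j = i + 1
        while j <= n and tuple(sym[i:j]) in phrases:
            j += 1
        phrases.add(tuple(sym[i : min(j, n)]))
        k += 1
        i = j
    if n == 1:
        return 0.0
    return float(k * math.log(n) / math.log(seq.levels) / n)


# ---------------------------------------------------------------------------
# frequency domain
# ---------------------------------------------------------------------------

def spectral_features(
    x: np.ndarray, fs: float, exclude_dc_peak: bool = True
) -> tuple[float, float, float, SpectralSummary]:
    """Peak frequency, magnitude-weighted centroid and bandwidth.

    The magnitude spectrum on nonnegative frequencies is treated as a mass
    distribution over frequency: the centre frequency is its mean, the
    bandwidth its standard deviation.  The peak is the frequency bin of
    largest magnitude, by default excluding the DC bin (a residual offset
    should not masquerade as a spectral peak); DC stays in the centroid and
    bandwidth sums.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ParameterError("need at least 2 samples for a spectrum")
    if not np.any(x):
        raise DegenerateSignalError("all-zero signal has no spectrum")
    mags = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    total = mags.sum()
    centre = float((freqs * mags).sum() / total)
    bandwidth = float(np.sqrt(((freqs - centre) ** 2 * mags).sum() / total))
    if exclude_dc_peak and len(mags) > 1:
        peak = float(freqs[1 + int(np.argmax(mags[1:]))])
    else:
        peak = float(freqs[int(np.argmax(mags))])
    return peak, centre, bandwidth, SpectralSummary(freqs=freqs, magnitudes=mags)


# ---------------------------------------------------------------------------
# time-frequency domain
# ---------------------------------------------------------------------------

def wavelet_features(
    x: np.ndarray, levels: int = 10, wavelet: str = "dmey"
) -> tuple[np.ndarray, float, np.ndarray, float]:
    """Wavelet level energies and wavelet entropy.

    Returns ``(level_energies, total_energy, relative_energies,
    wavelet_entropy)`` where energies are ordered ``(a_L, d_L, ..., d_1)``
    (approximation first, then details coarse to fine).  Each level's energy
    is the squared Euclidean norm of its coefficient vector; the wavelet
    entropy is the Shannon entropy (nats) of the relative energies.
    """
    x = np.asarray(x, dtype=float)
    if not np.any(x):
        raise DegenerateSignalError("all-zero signal has no energy distribution")
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(x), w.dec_len)
    use = min(levels, max_level)
    if use < 1:
        raise ParameterError(f"signal of length {len(x)} too short for any DWT level")
    if use < levels:
        logger.info(
            "reducing wavelet levels from %d to %d for signal of length %d",
            levels, use, len(x),
        )
    coeffs = pywt.wavedec(x, w, level=use, mode="periodization")
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = float(energies.sum())
    rel = energies / total
    nz = rel[rel > 0]
    entropy = float(-np.sum(nz * np.log(nz)))
    return energies, total, rel, entropy


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def extract_features(
    rec: MultiChannelRecording,
    segments: list[SwallowSegment],
    cfg: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Compute the full feature set for every segment x channel of a recording.

    Returns long-format rows (one per feature value) matching the cohort
    feature-table schema.  The duration is emitted once per swallow under the
    pseudo-channel ``ALL`` since all transducers share the segmentation.
    Degenerate segment signals yield NaN for the affected features and a log
    notice instead of an error.
    """
    cfg = cfg or FeatureConfig()
    if rec.subject is None:
        raise ParameterError("recording must carry subject metadata")
    meta = rec.subject
    rows: list[dict] = []

    def emit(swallow_idx: int, channel: str, feature: str, value: float) -> None:
        rows.append(
            {
                "subject_id": meta.subject_id,
                "sex": meta.sex,
                "age": meta.age,
                "swallow_idx": swallow_idx,
                "channel": channel,
                "feature": feature,
                "value": value,
            }
        )

    for si, seg in enumerate(segments):
        if seg.end > rec.n_samples:
            raise ParameterError(
                f"segment [{seg.start}, {seg.end}) exceeds recording length"
            )
        emit(si, "ALL", "duration_s", seg.duration_s)
        for channel, signal in rec.channels.items():
            x = signal[seg.slice()]
            values = _channel_features(x, rec.fs, cfg, channel, si)
            for feature, value in values.items():
                emit(si, channel, feature, value)

    df = pd.DataFrame(rows, columns=list(FEATURE_TABLE_COLUMNS))
    return df


def _channel_features(
    x: np.ndarray, fs: float, cfg: FeatureConfig, channel: str, swallow_idx: int
) -> dict[str, float]:
    out = {name: math.nan for name in PER_CHANNEL_FEATURES}
    try:
        out["skewness"], out["kurtosis"] = time_moments(x)
        q10 = quantize(x, cfg.entropy_levels)
        out["entropy_rate"] = entropy_rate(q10, cfg.max_pattern_len)
        q100 = quantize(x, cfg.lz_levels)
        out["lz_complexity"] = lz_complexity(q100)
        peak, centre, bw, _ = spectral_features(
            x, fs, exclude_dc_peak=cfg.exclude_dc_peak
        )
        out["peak_freq_hz"] = peak
        out["centre_freq_hz"] = centre
        out["bandwidth_hz"] = bw
        *_, went = wavelet_features(x, cfg.wavelet_levels, cfg.wavelet)
        out["wavelet_entropy"] = went
    except DegenerateSignalError as exc:
        logger.warning(
            "degenerate segment %d on channel %s: %s", swallow_idx, channel, exc
        )
    return out
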