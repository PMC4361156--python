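"""Swallow detection by two-class fuzzy c-means on local-variance features.

A swallow raises the local variance of the accelerometer signals by orders of
magnitude relative to the inter-swallow background, so the log of a
sliding-window variance separates "vibration" from "background" windows into
two well-separated clusters.  Fuzzy c-means with two classes labels each
window softly; runs of high-variance windows are mapped back to sample
coordinates, merged across short gaps, and pruned of spurious blips.  The
sound channel is never segmented on its own: it inherits the accelerometer
time points, which keeps the per-swallow pairing across transducers exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateSignalError, ParameterError
from .io import MultiChannelRecording

__all__ = [
    "SwallowSegment",
    "FcmResult",
    "SegmentConfig",
    "variance_features",
    "fuzzy_c_means",
    "extract_segments",
    "segment_recording",
]

#: log-variance assigned to exactly-constant windows, far below any real noise
LOG_VARIANCE_FLOOR = -80.0


@dataclass(frozen=True)
class SwallowSegment:
    """One detected swallow: half-open sample interval [start, end)."""

    start: int
    end: int
    duration_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment [{self.start}, {self.end})")
        if self.duration_s <= 0:
            raise ValueError(f"duration must be positive, got {self.duration_s}")

    @classmethod
    def from_samples(cls, start: int, end: int, fs: float) -> "SwallowSegment":
        return cls(start=int(start), end=int(end), duration_s=(end - start) / fs)

    def slice(self) -> slice:
        return slice(self.start, self.end)


@dataclass(frozen=True)
class FcmResult:
    """Two-class fuzzy c-means output on a 1-D feature sequence.

    ``memberships`` holds the membership of each window in the *high-variance*
    class; the complementary class membership is ``1 - memberships``.
    """

    centroids: tuple[float, float]  # (high, low)
    memberships: np.ndarray
    objective_trace: np.ndarray


@dataclass(frozen=True)
class SegmentConfig:
    """Windowing and decision parameters for swallow detection.

    The 25 ms window / 10 ms hop pair is much shorter than the ~2 s swallow
    but long enough for a stable variance estimate; the duration and gap
    thresholds reflect the physiological scale of a swallow.
    """

    window_s: float = 0.025
    hop_s: float = 0.010
    fuzzifier: float = 2.0
    tol: float = 1e-6
    max_iter: int = 300
    membership_cut: float = 0.5
    min_dur_s: float = 0.3
    min_gap_s: float = 0.5
    seed: int = 0


def variance_features(x: np.ndarray, window: int, hop: int) -> np.ndarray:
    """Log sliding-window variance, one value per hop position.

    Output length is ``floor((N - window) / hop) + 1``.  Windows with exactly
    zero variance are clamped to :data:`LOG_VARIANCE_FLOOR`.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if window < 2:
        raise ParameterError(f"window must be >= 2 samples, got {window}")
    if hop < 1:
        raise ParameterError(f"hop must be >= 1 sample, got {hop}")
    if window > n:
        raise ParameterError(f"window ({window}) longer than signal ({n})")
    n_win = (n - window) // hop + 1
    starts = np.arange(n_win) * hop
    # cumulative sums give O(N) window means/second moments
    c1 = np.concatenate(([0.0], np.cumsum(x)))
    c2 = np.concatenate(([0.0], np.cumsum(x * x)))
    s1 = c1[starts + window] - c1[starts]
    s2 = c2[starts + window] - c2[starts]
    var = s2 / window - (s1 / window) ** 2
    var = np.maximum(var, 0.0)  # guard tiny negative rounding
    out = np.full(n_win, LOG_VARIANCE_FLOOR)
    nz = var > 0
    out[nz] = np.log(var[nz])
    return np.maximum(out, LOG_VARIANCE_FLOOR)


def fuzzy_c_means(
    features: np.ndarray,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FcmResult:
    """Two-class fuzzy c-means on a scalar feature sequence.

    Standard alternating updates: memberships proportional to inverse squared
    distance to each centroid raised to ``1/(m-1)``, centroids as
    membership``^m``-weighted means; iteration stops when the centroid shift
    drops below ``tol``.  Classes are ordered so class 1 is the higher
    centroid and the returned memberships refer to it.
    """
    f = np.asarray(features, dtype=float)
    if f.ndim != 1 or len(f) < 2:
        raise ParameterError("need at least two feature values")
    if np.ptp(f) == 0:
        raise DegenerateSignalError("all feature values identical; cannot cluster")
    if fuzzifier <= 1:
        raise ParameterError(f"fuzzifier must exceed 1, got {fuzzifier}")

    rng = np.random.default_rng(seed)
    u_hi = rng.uniform(0.0, 1.0, size=len(f))  # membership in class "high"
    centroids = np.array([f.max(), f.min()])
    trace: list[float] = []
    m = fuzzifier
    for _ in range(max_iter):
        u = np.stack([u_hi, 1.0 - u_hi])  # (2, n)
        um = u**m
        new_centroids = um @ f / um.sum(axis=1)
        d2 = (f[None, :] - new_centroids[:, None]) ** 2
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=0)
        trace.append(float(np.sum(u_new**m * d2)))
        shift = float(np.max(np.abs(new_centroids - centroids)))
        centroids = new_centroids
        u_hi = u_new[0]
        if shift < tol:
            break
    order = np.argsort(centroids)[::-1]  # class 1 = higher centroid
    centroids = centroids[order]
    if order[0] == 1:
        u_hi = 1.0 - u_hi
    return FcmResult(
        centroids=(float(centroids[0]), float(centroids[1])),
        memberships=u_hi,
        objective_trace=np.asarray(trace),
    )


def extract_segments(
    fcm: FcmResult,
    window: int,
    hop: int,
    fs: float,
    membership_cut: float = 0.5,
    min_dur_s: float = 0.3,
    min_gap_s: float = 0.5,
) -> list[SwallowSegment]:
    """Turn per-window memberships into disjoint swallow segments.

    Windows with high-class membership above ``membership_cut`` are active.
    Each window is identified with its centre sample; an active run spans
    from the first active centre minus half a window to the last active
    centre plus half a window.  Runs closer than ``min_gap_s`` are merged,
    then runs shorter than ``min_dur_s`` are dropped.
    """
    active = fcm.memberships > membership_cut
    if not np.any(active):
        return []
    idx = np.flatnonzero(active)
    # split into consecutive runs of active windows
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [len(idx) - 1]))
    half = window // 2
    intervals = []
    for a, b in zip(run_starts, run_ends):
        centre_first = idx[a] * hop + half
        centre_last = idx[b] * hop + half
        intervals.append([centre_first - half, centre_last + half])

    merged: list[list[int]] = []
    gap = int(round(min_gap_s * fs))
    for lo, hi in intervals:
        if merged and lo - merged[-1][1] < gap:
            merged[-1][1] = hi
        else:
            merged.append([lo, hi])

    min_len = min_dur_s * fs
    out = []
    for lo, hi in merged:
        if hi - lo >= min_len:
            out.append(SwallowSegment.from_samples(max(lo, 0), hi, fs))
    return out


def segment_recording(
    rec: MultiChannelRecording, cfg: SegmentConfig | None = None
) -> list[SwallowSegment]:
    """Detect swallows on the accelerometer channels of a (conditioned) recording.

    When both axes are present the detection signal is the sum of the squared
    unit-variance-normalised axes, so neither axis dominates; with a single
    axis that axis is used alone.  The returned segments apply to every
    channel, including SOUND.
    """
    cfg = cfg or SegmentConfig()
    axes = [rec.channels[name] for name in ("AP", "SI") if name in rec.channels]
    if not axes:
        raise ConfigurationError(
            "segmentation requires an accelerometer channel (AP and/or SI)"
        )
    parts = []
    for x in axes:
        sd = np.std(x)
        if sd == 0:
            raise DegenerateSignalError("accelerometer channel is constant")
        parts.append((x / sd) ** 2)
    detection = np.sum(parts, axis=0)

    window = max(2, int(round(cfg.window_s * rec.fs)))
    hop = max(1, int(round(cfg.hop_s * rec.fs)))
    feats = variance_features(detection, window, hop)
    fcm = fuzzy_c_means(
        feats,
        fuzzifier=cfg.fuzzifier,
        tol=cfg.tol,
        max_iter=cfg.max_iter,
        seed=cfg.seed,
    )
    segs = extract_segments(
        fcm,
        window=window,
        hop=hop,
        fs=rec.fs,
        membership_cut=cfg.membership_cut,
        min_dur_s=cfg.min_dur_s,
        min_gap_s=cfg.min_gap_s,
    )
    return [
        SwallowSegment.from_samples(s.start, min(s.end, rec.n_samples), rec.fs)
        for s in segs
    ]
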