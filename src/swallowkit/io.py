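"""Reading and writing of recordings, segment annotations and feature tables.

The on-disk interchange formats are deliberately plain text:

* recordings — one CSV per recording, a header row naming the channels
  (``AP``, ``SI``, ``SOUND``), one sample per row, optional leading ``time``
  column; WAV is accepted as a convenience with channel names supplied by the
  caller, since WAV tracks are anonymous;
* swallow segments — a JSON list of ``{"start", "end", "duration_s"}``;
* cohort feature tables — long-format CSV with one row per
  (subject, swallow, channel, feature) value.

Sample indices are 0-based throughout and segment intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    FormatError,
    NamingError,
    SamplingError,
)

#: Channel names recognised by the pipeline: anterior-posterior accelerometer,
#: superior-inferior accelerometer, contact-microphone sound.
CHANNEL_NAMES = ("AP", "SI", "SOUND")

#: Column order of the long-format cohort feature table.
FEATURE_TABLE_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "swallow_idx",
    "channel",
    "feature",
    "value",
)

_TIME_COLUMN_ALIASES = {"time", "t", "time_s", "seconds"}


@dataclass(frozen=True)
class SubjectMeta:
    """Demographics attached to one recording's subject."""

    subject_id: str
    sex: str  # "male" | "female"
    age: float  # years

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 0:
            raise ValueError(f"age must be nonnegative, got {self.age}")


@dataclass
class MultiChannelRecording:
    """Synchronised multi-channel recording of one swallowing task.

    Parameters
    ----------
    fs
        Sampling rate in Hz, shared by all channels.
    channels
        Ordered mapping of channel name -> 1-D float array.  Names must be
        drawn from :data:`CHANNEL_NAMES`; all arrays must share one length.
    subject
        Optional subject demographics.
    """

    fs: float
    channels: dict[str, np.ndarray]
    subject: SubjectMeta | None = field(default=None)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            raise ValueError("recording must contain at least one channel")
        for name in self.channels:
            if name not in CHANNEL_NAMES:
                raise NamingError(
                    f"unknown channel {name!r}; expected one of {CHANNEL_NAMES}"
                )
        self.channels = {
            name: np.asarray(x, dtype=float) for name, x in self.channels.items()
        }
        lengths = {name: x.shape for name, x in self.channels.items()}
        for name, shape in lengths.items():
            if len(shape) != 1:
                raise ValueError(f"channel {name!r} is not 1-D: shape {shape}")
        n = {shape[0] for shape in lengths.values()}
        if len(n) != 1:
            raise ValueError(f"channels have unequal lengths: {lengths}")
        if n.pop() < 1:
            raise ValueError("channels must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_channels(self, channels: dict[str, np.ndarray]) -> "MultiChannelRecording":
        """Return a copy of this recording with the given channel data."""
        return MultiChannelRecording(fs=self.fs, channels=channels, subject=self.subject)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    fs_override: float | None = None,
    channel_names: list[str] | None = None,
    subject: SubjectMeta | None = None,
) -> MultiChannelRecording:
    """Read a recording from CSV or WAV.

    CSV files carry channel names in the header and, optionally, a leading
    time column (validated as uniform); the sampling rate then comes from the
    time column unless ``fs_override`` is given.  WAV files carry ``fs`` in
    the header but no channel names, so ``channel_names`` is required, one
    name per track in order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".wav":
        return _read_wav(path, fs_override, channel_names, subject)
    return _read_csv(path, fs_override, channel_names, subject)


def _read_csv(path, fs_override, channel_names, subject):
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: malformed CSV ({exc})") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows (missing fields)")

    cols = list(df.columns)
    time = None
    if cols and cols[0].strip().lower() in _TIME_COLUMN_ALIASES:
        time = df[cols[0]].to_numpy(dtype=float)
        cols = cols[1:]
    if channel_names is not None:
        if len(channel_names) != len(cols):
            raise NamingError(
                f"{path}: {len(cols)} data columns but {len(channel_names)} names given"
            )
        rename = dict(zip(cols, channel_names))
        df = df.rename(columns=rename)
        cols = channel_names

    fs = fs_override
    if time is not None:
        if len(time) > 1:
            dt = np.diff(time)
            if dt.min() <= 0 or not np.allclose(dt, dt.mean(), rtol=1e-6, atol=1e-12):
                raise SamplingError(f"{path}: time column is not uniformly sampled")
            fs_time = 1.0 / dt.mean()
            if fs is None:
                fs = fs_time
            elif not np.isclose(fs, fs_time, rtol=1e-3):
                raise SamplingError(
                    f"{path}: time column implies fs={fs_time:.6g} Hz, "
                    f"inconsistent with requested {fs:.6g} Hz"
                )
        elif fs is None:
            raise SamplingError(f"{path}: cannot infer fs from a single sample")
    if fs is None:
        raise SamplingError(f"{path}: no time column; pass fs_override")

    channels = {c: df[c].to_numpy(dtype=float) for c in cols}
    return MultiChannelRecording(fs=float(fs), channels=channels, subject=subject)


def _read_wav(path, fs_override, channel_names, subject):
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    if fs_override is not None:
        fs = fs_override
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 1 and data.ndim == 2 and data.shape[1] > data.shape[0]:
        data = data.T  # mono comes back 1-D
    n_tracks = data.shape[1]
    if channel_names is None:
        raise NamingError(f"{path}: WAV tracks are unnamed; pass channel_names")
    if len(channel_names) != n_tracks:
        raise NamingError(
            f"{path}: {n_tracks} tracks but {len(channel_names)} names given"
        )
    channels = {name: data[:, i] for i, name in enumerate(channel_names)}
    return MultiChannelRecording(fs=float(fs), channels=channels, subject=subject)


def write_recording(
    rec: MultiChannelRecording, path: str | Path, include_time: bool = False
) -> None:
    """Write a recording as a channel-per-column CSV (value-exact roundtrip)."""
    path = Path(path)
    data = {}
    if include_time:
        data["time"] = np.arange(rec.n_samples) / rec.fs
    data.update(rec.channels)
    # %.17g guarantees exact float64 roundtrip
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def write_segments(segments, path: str | Path, fs: float | None = None) -> None:
    """Write swallow segments as a JSON list of {start, end, duration_s}."""
    payload = {
        "fs": fs,
        "segments": [
            {"start": int(s.start), "end": int(s.end), "duration_s": float(s.duration_s)}
            for s in segments
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_segments(path: str | Path):
    """Read a segments JSON written by :func:`write_segments`."""
    from .segment import SwallowSegment

    payload = json.loads(Path(path).read_text())
    fs = payload.get("fs")
    segs = []
    for item in payload["segments"]:
        if fs:
            segs.append(SwallowSegment.from_samples(item["start"], item["end"], fs))
        else:
            segs.append(
                SwallowSegment(
                    start=item["start"], end=item["end"], duration_s=item["duration_s"]
                )
            )
    return segs


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def sort_feature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Canonical bit-stable ordering: subject, swallow, channel, feature."""
    return table.sort_values(
        ["subject_id", "swallow_idx", "channel", "feature"],
        kind="mergesort",  # stable
    ).reset_index(drop=True)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format cohort feature table as CSV.

    An empty table yields a header-only file.  Rows are emitted in the
    canonical (subject, swallow, channel, feature) order so repeated writes
    are bit-stable.
    """
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ConfigurationError(f"feature table missing columns {missing}")
    out = table.loc[:, list(FEATURE_TABLE_COLUMNS)]
    if len(out):
        out = sort_feature_table(out)
    out.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV back into a DataFrame."""
    df = pd.read_csv(
        path,
        float_precision="round_trip",
        dtype={
            "subject_id": str,
            "sex": str,
            "channel": str,
            "feature": str,
        },
    )
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: not a feature table (missing {missing})")
    return df


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Read a JSON configuration file into a plain dict."""
    try:
        cfg = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config root must be a JSON object")
    return cfg
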