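"""Recording, event-table, feature-table and image I/O.

Signals travel as :class:`RawRecording`: a channels-by-time matrix in
microvolts plus sampling rate, channel names and a keypress event table.
Two on-disk layouts are supported:

* ``edf`` — a 16-bit EDF file (read through :mod:`mne`); events live in a
  ``<stem>.events.tsv`` sidecar because plain EDF has no annotation track.
* ``plain`` — a whitespace-delimited numeric matrix (one row per channel)
  plus the same TSV event sidecar and a small JSON header sidecar.

Event onsets are stored in seconds as floats; conversion to sample indices
happens once, at epoching.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "FeatureSet",
    "read_recording",
    "write_recording",
    "read_feature_table",
    "write_feature_table",
]

EVENT_COLUMNS = ("onset_s", "label")


@dataclass
class RawRecording:
    """Multichannel EEG signal with events.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        Unique channel labels (10-20 names such as ``"Fz"``).
    events : pandas.DataFrame
        Columns ``onset_s`` (float seconds) and ``label`` (str).
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    events: pd.DataFrame = field(default_factory=lambda: _empty_events())

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} signal rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        self.events = self.events.reset_index(drop=True)
        if list(self.events.columns[:2]) != list(EVENT_COLUMNS):
            raise ValueError(f"event table needs columns {EVENT_COLUMNS}")
        if len(self.events):
            onsets = self.events["onset_s"].to_numpy(dtype=float)
            if (onsets < 0).any() or (onsets > self.duration).any():
                bad = onsets[(onsets < 0) | (onsets > self.duration)][0]
                raise ValueError(
                    f"event onset {bad:g} s outside recording [0, {self.duration:g}] s"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.shape[1] / self.fs

    def channel_index(self, name: str) -> int:
        """Locate a channel by name (order-independent)."""
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None

    def copy(self) -> "RawRecording":
        return RawRecording(
            self.samples.copy(), self.fs, list(self.channel_names), self.events.copy()
        )


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame({"onset_s": pd.Series(dtype=float), "label": pd.Series(dtype=str)})


@dataclass
class FeatureSet:
    """Deep-spectrum feature vectors with group/session labels.

    ``vectors`` is (n_instances, n_features); ``labels`` carries at least
    ``subject``, ``group`` (tinnitus/control) and ``session`` (S1/S2).
    """

    vectors: np.ndarray
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if len(self.labels) != self.vectors.shape[0]:
            raise ValueError(
                f"{len(self.labels)} label rows for {self.vectors.shape[0]} vectors"
            )
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def cell(self, group: str, session: str) -> np.ndarray:
        """Vectors belonging to one group x session cell."""
        mask = (self.labels["group"] == group) & (self.labels["session"] == session)
        return self.vectors[mask.to_numpy()]


# ---------------------------------------------------------------------------
# recording I/O


def write_recording(rec: RawRecording, path: str | Path, format: str = "plain") -> Path:
    """Write a recording plus its event sidecar; returns the main path."""
    path = Path(path)
    if format == "plain":
        _write_plain(rec, path)
    elif format == "edf":
        _write_edf(rec, path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'plain')")
    _write_events_sidecar(rec.events, _sidecar_path(path))
    return path


def read_recording(path: str | Path, format: str = "plain") -> RawRecording:
    """Read a recording written by :func:`write_recording`.

    A missing event sidecar yields an empty event table with a warning,
    mirroring recordings whose response log was lost.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "plain":
        samples, fs, names = _read_plain(path)
    elif format == "edf":
        samples, fs, names = _read_edf(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'edf' or 'plain')")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        events = _read_events_sidecar(sidecar)
    else:
        warnings.warn(f"no event sidecar at {sidecar}; event table left empty")
        events = _empty_events()
    return RawRecording(samples, fs, names, events)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".events.tsv")


def _write_events_sidecar(events: pd.DataFrame, path: Path) -> None:
    events[list(EVENT_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.9g")


def _read_events_sidecar(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - depends on corruption mode
        raise ValueError(f"malformed event sidecar {path}: {exc}") from exc
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"event sidecar {path} missing column {col!r}")
    df["onset_s"] = df["onset_s"].astype(float)
    df["label"] = df["label"].astype(str)
    return df[list(EVENT_COLUMNS)]


# -- plain layout -----------------------------------------------------------


def _write_plain(rec: RawRecording, path: Path) -> None:
    np.savetxt(path, rec.samples, fmt="%.9e")
    header = {"fs": rec.fs, "channel_names": rec.channel_names}
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def _read_plain(path: Path) -> tuple[np.ndarray, float, list[str]]:
    header_path = path.with_suffix(".json")
    if not header_path.exists():
        raise ValueError(f"plain layout header {header_path} missing")
    try:
        header = json.loads(header_path.read_text())
        fs = float(header["fs"])
        names = [str(n) for n in header["channel_names"]]
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"malformed plain-layout header {header_path}: {exc}") from exc
    samples = np.loadtxt(path, ndmin=2)
    if samples.shape[0] != len(names):
        raise ValueError(
            f"{path}: {samples.shape[0]} signal rows but header names {len(names)} channels"
        )
    return samples, fs, names


# -- EDF --------------------------------------------------------------------
#
# Writer emits a minimal single-record EDF (16-bit, physical dimension uV).
# Reading goes through mne, which also validates the writer's headers.


def _write_edf(rec: RawRecording, path: Path) -> None:
    ns = rec.n_channels
    n_times = rec.n_times
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    # one data record per second; pad the tail with the final value
    record_len = int(round(fs))
    n_records = int(np.ceil(n_times / record_len))
    padded = np.empty((ns, n_records * record_len))
    padded[:, :n_times] = rec.samples
    padded[:, n_times:] = rec.samples[:, -1:]

    phys_min = np.floor(padded.min(axis=1))
    phys_max = np.ceil(padded.max(axis=1))
    same = phys_max <= phys_min
    phys_max[same] = phys_min[same] + 1.0
    dig_min, dig_max = -32768, 32767
    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((padded - phys_min[:, None]) / scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF header field too long: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Synthetic EEG", 80),
            pad("01.01.00", 8),
            pad("00.00.00", 8),
            pad(str(256 + ns * 256), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    sig_header = b"".join(
        [
            b"".join(pad(n, 16) for n in rec.channel_names),
            b"".join(pad("EEG", 80) for _ in range(ns)),
            b"".join(pad("uV", 8) for _ in range(ns)),
            b"".join(pad(f"{phys_min[i]:g}", 8) for i in range(ns)),
            b"".join(pad(f"{phys_max[i]:g}", 8) for i in range(ns)),
            b"".join(pad(str(dig_min), 8) for _ in range(ns)),
            b"".join(pad(str(dig_max), 8) for _ in range(ns)),
            b"".join(pad("", 80) for _ in range(ns)),
            b"".join(pad(str(record_len), 8) for _ in range(ns)),
            b"".join(pad("", 32) for _ in range(ns)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_records):
            block = digital[:, r * record_len : (r + 1) * record_len]
            fh.write(block.tobytes())
    # stash true length so reads can trim record padding
    path.with_suffix(".json").write_text(
        json.dumps({"n_times": n_times, "fs": fs, "channel_names": rec.channel_names})
    )


def _read_edf(path: Path) -> tuple[np.ndarray, float, list[str]]:
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise ValueError(f"malformed EDF file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # mne scales EEG to volts; recover uV
    fs = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    meta_path = path.with_suffix(".json")
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        n_times = int(meta.get("n_times", data.shape[1]))
        data = data[:, :n_times]
    return data, fs, names


def edf_quantization_step(rec: RawRecording) -> np.ndarray:
    """Per-channel amplitude resolution of the 16-bit EDF encoding."""
    lo = np.floor(rec.samples.min(axis=1))
    hi = np.ceil(rec.samples.max(axis=1))
    hi = np.where(hi <= lo, lo + 1.0, hi)
    return (hi - lo) / 65535.0


# ---------------------------------------------------------------------------
# feature tables


def write_feature_table(features: FeatureSet, path: str | Path) -> Path:
    """CSV with subject/group/session labels and ``f0001..fNNNN`` columns."""
    path = Path(path)
    n_feat = features.n_features
    width = max(4, len(str(n_feat)))
    cols = [f"f{i + 1:0{width}d}" for i in range(n_feat)]
    label_cols = ["subject", "group", "session"]
    for col in label_cols:
        if col not in features.labels.columns:
            raise ValueError(f"feature labels missing column {col!r}")
    df = pd.concat(
        [
            features.labels[label_cols].reset_index(drop=True),
            pd.DataFrame(features.vectors, columns=cols),
        ],
        axis=1,
    )
    if len(features) == 0:
        df = pd.DataFrame(columns=label_cols + cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> FeatureSet:
    df = pd.read_csv(path)
    label_cols = ["subject", "group", "session"]
    feat_cols = [c for c in df.columns if c not in label_cols]
    vectors = df[feat_cols].to_numpy(dtype=float)
    if len(df) == 0:
        vectors = vectors.reshape(0, len(feat_cols))
    return FeatureSet(vectors=vectors, labels=df[label_cols].copy())
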