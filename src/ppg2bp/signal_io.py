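"""Waveform and beat containers, plus plain-text I/O for records, beat
datasets, fitted models and evaluation reports.

The on-disk beat format is a single long-form CSV with one row per sample:

    subject_id, segment_id, beat_id, channel, sample_index, value, fs, filtered

which is diff-able, schema-checked on read, and loses nothing but float
text precision. Models are JSON (the GRNN's "weights" are its training
matrices); reports are JSON plus a human-readable text rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

CHANNELS = ("PPG", "ABP")

#: default units per channel: PPG is in arbitrary units, ABP in mmHg
CHANNEL_UNITS = {"PPG": "a.u.", "ABP": "mmHg"}

#: records longer than this are truncated on read when truncation is enabled
MAX_RECORD_SAMPLES = 1000

BEAT_CSV_COLUMNS = [
    "subject_id",
    "segment_id",
    "beat_id",
    "channel",
    "sample_index",
    "value",
    "fs",
    "filtered",
]


@dataclass
class WaveformRecord:
    """A continuous single-channel waveform for one subject.

    ``filtered`` marks a signal whose DC component has been removed by
    band-pass filtering; BP-range rules are meaningless on such signals
    and downstream code checks the flag.
    """

    subject_id: str
    signal: np.ndarray
    fs: float = 125.0
    units: str = ""
    channel: str = "PPG"
    filtered: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if not self.units:
            self.units = CHANNEL_UNITS[self.channel]
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.signal.ndim != 1 or self.signal.size < 2:
            raise ValueError("signal must be a 1-D sequence of length >= 2")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.signal.size / self.fs


@dataclass
class Beat:
    """One single-period (foot-to-foot) waveform segment."""

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    segment_id: str = ""
    beat_id: int = 0
    channel: str = "PPG"
    filtered: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("beat samples must be 1-D")
        # no beat shorter than 250 ms
        if self.samples.size < 0.25 * self.fs:
            raise ValueError(
                f"beat of {self.samples.size} samples at {self.fs} Hz is shorter "
                "than the 250 ms minimum"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("beat contains non-finite samples")

    @property
    def period_s(self) -> float:
        """Beat period in seconds (length / fs, exactly)."""
        return self.samples.size / self.fs

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.segment_id, self.beat_id)


@dataclass
class BeatPair:
    """A time-aligned PPG beat and BP beat from the same subject/segment."""

    ppg: Beat
    bp: Beat

    def __post_init__(self) -> None:
        if self.ppg.subject_id != self.bp.subject_id:
            raise ValueError("paired beats must share a subject_id")
        if self.ppg.segment_id != self.bp.segment_id:
            raise ValueError("paired beats must come from the same segment")

    @property
    def subject_id(self) -> str:
        return self.ppg.subject_id

    @property
    def segment_id(self) -> str:
        return self.ppg.segment_id

    @property
    def key(self) -> tuple[str, str, int]:
        return self.ppg.key


def read_record(
    path: str | Path,
    channel: str = "PPG",
    fs: float = 125.0,
    subject_id: str | None = None,
    truncate: bool = True,
    max_samples: int = MAX_RECORD_SAMPLES,
) -> WaveformRecord:
    """Read a one-column plain-text/CSV waveform file into a record.

    With ``truncate`` enabled (the default) only the first ``max_samples``
    samples are kept, matching the curation convention of keeping each
    instance's first 1000 samples.

    Raises ``ValueError`` naming the offending row for non-numeric content,
    and rejects empty or non-finite signals outright.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"waveform file not found: {path}")
    df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True)
    if df.shape[1] != 1:
        raise ValueError(
            f"{path} has {df.shape[1]} columns; expected a single numeric column"
        )
    values = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    bad = values.index[values.isna() & df.iloc[:, 0].notna()]
    if len(bad) > 0:
        row = int(bad[0])
        raise ValueError(
            f"non-numeric value {df.iloc[row, 0]!r} at row {row} of {path}"
        )
    if values.isna().any():
        row = int(values.index[values.isna()][0])
        raise ValueError(f"missing/NaN sample at row {row} of {path}")
    signal = values.to_numpy(dtype=float)
    if truncate and signal.size > max_samples:
        signal = signal[:max_samples]
    return WaveformRecord(
        subject_id=subject_id if subject_id is not None else path.stem,
        signal=signal,
        fs=fs,
        channel=channel,
    )


def read_physionet_record(record_name: str, channel: str = "PPG") -> WaveformRecord:
    """Read a PhysioNet-format waveform record (optional feature).

    Requires the ``wfdb`` package (install the ``physionet`` extra). Signal
    names are matched case-insensitively against the requested channel
    ("PPG" also matches "PLETH").
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading PhysioNet records requires the optional 'wfdb' package; "
            "install ppg2bp[physionet]"
        ) from exc
    rec = wfdb.rdrecord(record_name)  # pragma: no cover
    aliases = {"PPG": {"PPG", "PLETH"}, "ABP": {"ABP", "BP", "ART"}}[channel]
    names = [str(n).upper() for n in rec.sig_name]
    for i, name in enumerate(names):  # pragma: no cover
        if name in aliases:
            sig = np.asarray(rec.p_signal[:, i], dtype=float)
            sig = sig[np.isfinite(sig)]
            return WaveformRecord(
                subject_id=Path(record_name).stem, signal=sig, fs=float(rec.fs),
                channel=channel,
            )
    raise ValueError(  # pragma: no cover
        f"channel {channel!r} not found in record {record_name} (signals: {rec.sig_name})"
    )


def write_beats(pairs: list[BeatPair], path: str | Path) -> None:
    """Write beat pairs to the long-form CSV format (lossless round-trip)."""
    rows: list[dict] = []
    for pair in pairs:
        for beat in (pair.ppg, pair.bp):
            for i, v in enumerate(beat.samples):
                rows.append(
                    {
                        "subject_id": beat.subject_id,
                        "segment_id": beat.segment_id,
                        "beat_id": beat.beat_id,
                        "channel": beat.channel,
                        "sample_index": i,
                        "value": v,
                        "fs": beat.fs,
                        "filtered": int(beat.filtered),
                    }
                )
    df = pd.DataFrame(rows, columns=BEAT_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_beats(path: str | Path) -> list[BeatPair]:
    """Read beat pairs written by :func:`write_beats`.

    Preserves the original sample order (sorted by sample_index within each
    beat; never resampled). A beat with a missing channel is a schema error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"beat file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in BEAT_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns: {missing}")
    if df.empty:
        return []
    pairs: list[BeatPair] = []
    keys = df[["subject_id", "segment_id", "beat_id"]].drop_duplicates()
    grouped = df.groupby(["subject_id", "segment_id", "beat_id"], sort=False)
    for key_row in keys.itertuples(index=False):
        key = (key_row.subject_id, key_row.segment_id, key_row.beat_id)
        g = grouped.get_group(key)
        beats = {}
        for channel, sub in g.groupby("channel", sort=False):
            sub = sub.sort_values("sample_index")
            idx = sub["sample_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                raise ValueError(f"non-contiguous sample indices for beat {key}")
            beats[channel] = Beat(
                samples=sub["value"].to_numpy(dtype=float),
                fs=float(sub["fs"].iloc[0]),
                subject_id=str(key[0]),
                segment_id=str(key[1]),
                beat_id=int(key[2]),
                channel=str(channel),
                filtered=bool(sub["filtered"].iloc[0]),
            )
        if "PPG" not in beats or "ABP" not in beats:
            raise ValueError(
                f"beat {key} lacks a {'PPG' if 'PPG' not in beats else 'ABP'} channel"
            )
        pairs.append(BeatPair(ppg=beats["PPG"], bp=beats["ABP"]))
    return pairs


MODEL_FORMAT_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted :class:`~ppg2bp.grnn.GRNNRegressor` to JSON."""
    from ppg2bp.grnn import GRNNRegressor  # local import avoids cycle

    if not isinstance(model, GRNNRegressor):
        raise TypeError("save_model expects a GRNNRegressor")
    if not hasattr(model, "X_train_"):
        raise ValueError("model is not fitted")
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "delta": model.delta,
        "standardize": model.standardize,
        "X_train": model.X_train_.tolist(),
        "Y_train": model.Y_train_.tolist(),
        "mean": model.mean_.tolist(),
        "scale": model.scale_.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    """Load a GRNN model written by :func:`save_model`."""
    from ppg2bp.grnn import GRNNRegressor

    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    model = GRNNRegressor(delta=payload["delta"], standardize=payload["standardize"])
    model.X_train_ = np.asarray(payload["X_train"], dtype=float)
    model.Y_train_ = np.asarray(payload["Y_train"], dtype=float)
    model.mean_ = np.asarray(payload["mean"], dtype=float)
    model.scale_ = np.asarray(payload["scale"], dtype=float)
    model.n_features_in_ = model.X_train_.shape[1]
    return model


def save_report(report_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=2))


def load_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
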