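"""Reading, writing and re-referencing multichannel biopotential recordings.

Cutaneous electrogastrogram (EGG) recordings are stored as plain CSV/TSV
tables (one row per sample, one column per channel, values in microvolts)
accompanied by a JSON sidecar carrying the sampling rate, units, electrode
layout and recording reference.  Event logs (meals, sleep, symptoms) are
JSON-lines, one event per line, timestamped in seconds from the start of
the recording.

Electrode layout convention: positions in cm on the abdominal surface,
x positive toward the subject's left, y positive toward the head, origin
at the midline reference electrode (halfway between xiphoid process and
umbilicus).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EVENT_TAGS",
    "Event",
    "EventLog",
    "BipolarSignal",
    "MultichannelRecording",
    "read_recording",
    "write_recording",
    "read_event_log",
    "write_event_log",
    "downsample",
    "rereference",
    "traditional_pair",
]

#: Controlled vocabulary for event tags; anything else is coerced to "other".
EVENT_TAGS = frozenset(
    {
        "meal",
        "snack",
        "bowel_movement",
        "sleep_onset",
        "wake_onset",
        "symptom",
        "exercise",
        "other",
    }
)

# Analysis band for gastric activity (Hz); the top edge sets the minimum
# admissible sampling rate after decimation.
ANALYSIS_BAND_TOP_HZ = 0.20


@dataclass(frozen=True)
class Event:
    """A logged event, timestamped in seconds from recording start."""

    time_s: float
    tag: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.tag not in EVENT_TAGS:
            object.__setattr__(self, "note", f"[{self.tag}] {self.note}".strip())
            object.__setattr__(self, "tag", "other")


@dataclass
class EventLog:
    """Time-sorted list of subject-logged events."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time_s)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def with_tag(self, tag: str) -> list[Event]:
        return [e for e in self.events if e.tag == tag]


@dataclass
class BipolarSignal:
    """A single re-referenced time series in microvolts.

    This is the observed signal ``y`` that enters artifact rejection:
    the difference between a measurement electrode and a reference
    electrode.
    """

    samples: np.ndarray
    fs: float
    measurement_label: str = "measurement"
    reference_label: str = "reference"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("bipolar signal must be one-dimensional")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass
class MultichannelRecording:
    """Channels x time matrix of biopotentials in microvolts."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    reference_label: str | None = None
    layout: dict[str, tuple[float, float]] | None = None
    start_time: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.layout is not None:
            missing = set(self.channel_labels) - set(self.layout)
            if missing:
                raise ValueError(f"layout missing channels: {sorted(missing)}")
            self.layout = {
                k: (float(x), float(y))
                for k, (x, y) in self.layout.items()
                if k in self.channel_labels
            }

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None
        return self.samples[idx]


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
) -> MultichannelRecording:
    """Read a recording from a delimited text file plus its JSON sidecar.

    Parameters
    ----------
    path
        CSV or TSV file.  A header row names the channels; an optional
        leading ``time`` or ``sample`` column is used to check monotonicity
        and, if the sidecar lacks one, to infer the sampling rate.
    format
        ``"csv"`` or ``"tsv"``; inferred from the extension when omitted.
    fs
        Overrides the sidecar sampling rate (CLI ``--fs``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv")
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ValueError(f"malformed recording file {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"malformed recording file {path}: ragged or missing values")

    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())

    time_col = None
    for cand in ("time", "time_s", "t", "sample"):
        if cand in df.columns:
            time_col = cand
            break
    if time_col is not None:
        tvals = df[time_col].to_numpy(dtype=float)
        if tvals.size > 1 and not np.all(np.diff(tvals) > 0):
            raise ValueError(f"non-monotonic {time_col} column in {path}")

    if fs is None:
        fs = meta.get("fs")
    if fs is None and time_col in ("time", "time_s", "t") and len(df) > 1:
        dt = np.diff(df[time_col].to_numpy(dtype=float))
        if np.allclose(dt, dt[0], rtol=1e-6):
            fs = 1.0 / dt[0]
    if fs is None:
        raise ValueError(
            f"sampling rate unavailable: no sidecar {sc.name} entry, no usable "
            "time column, and no --fs override"
        )

    chan_cols = [c for c in df.columns if c != time_col]
    if not chan_cols:
        raise ValueError(f"no channel columns in {path}")
    samples = df[chan_cols].to_numpy(dtype=float).T
    layout = meta.get("layout")
    if layout is not None:
        layout = {k: (float(v[0]), float(v[1])) for k, v in layout.items()}
    return MultichannelRecording(
        samples=samples,
        fs=float(fs),
        channel_labels=chan_cols,
        reference_label=meta.get("reference"),
        layout=layout,
        start_time=meta.get("start_time"),
    )


def write_recording(
    rec: MultichannelRecording, path: str | Path, format: str | None = None
) -> Path:
    """Write a recording to CSV/TSV plus a JSON sidecar; round-trips exactly.

    Floats are printed with 17 significant digits so that reading the file
    back reproduces every sample bit-exactly.
    """
    path = Path(path)
    fmt = format or ("tsv" if path.suffix.lower() in {".tsv", ".tab"} else "csv")
    sep = "\t" if fmt == "tsv" else ","
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.insert(0, "sample", np.arange(rec.n_samples))
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")
    meta = {
        "fs": rec.fs,
        "units": "uV",
        "reference": rec.reference_label,
        "layout": {k: list(v) for k, v in rec.layout.items()} if rec.layout else None,
        "start_time": rec.start_time,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_event_log(path: str | Path) -> EventLog:
    """Read a JSON-lines event log (one ``{"time_s", "tag", "note"}`` per line)."""
    events = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        d = json.loads(line)
        events.append(Event(float(d["time_s"]), d["tag"], d.get("note", "")))
    return EventLog(events)


def write_event_log(log: EventLog, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        for e in log:
            fh.write(json.dumps({"time_s": e.time_s, "tag": e.tag, "note": e.note}))
            fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# Resampling and re-referencing
# ---------------------------------------------------------------------------

def downsample(
    rec: MultichannelRecording, target_fs: float
) -> MultichannelRecording:
    """Anti-alias low-pass filter and decimate to ``target_fs``.

    The decimation factor must be an integer (e.g. 250 Hz -> 5 Hz, factor
    50) and the target rate must keep the 0.02-0.20 Hz gastric analysis
    band below Nyquist.  The anti-alias filter is a zero-phase FIR low-pass
    with cutoff at 0.4 x target_fs, so the analysis band is passed without
    phase distortion.
    """
    if not target_fs > 0:
        raise ValueError("target_fs must be positive")
    factor_f = rec.fs / target_fs
    factor = int(round(factor_f))
    if not math.isclose(factor_f, factor, rel_tol=1e-9) or factor < 1:
        raise ValueError(
            f"target_fs {target_fs} does not evenly divide fs {rec.fs}"
        )
    if target_fs < 2 * ANALYSIS_BAND_TOP_HZ:
        raise ValueError(
            f"target_fs {target_fs} Hz cannot represent the analysis band "
            f"(needs >= {2 * ANALYSIS_BAND_TOP_HZ} Hz)"
        )
    if factor == 1:
        return MultichannelRecording(
            rec.samples.copy(), rec.fs, list(rec.channel_labels),
            rec.reference_label, rec.layout, rec.start_time,
        )
    numtaps = 16 * factor + 1
    taps = sps.firwin(numtaps, 0.4 * target_fs, fs=rec.fs, window="hamming")
    padlen = min(3 * numtaps, rec.n_samples - 1)
    filtered = sps.filtfilt(taps, [1.0], rec.samples, axis=-1, padlen=padlen)
    return MultichannelRecording(
        samples=filtered[:, ::factor],
        fs=target_fs,
        channel_labels=list(rec.channel_labels),
        reference_label=rec.reference_label,
        layout=rec.layout,
        start_time=rec.start_time,
    )


def rereference(
    rec: MultichannelRecording, measurement: str, reference: str
) -> BipolarSignal:
    """Form a bipolar signal by subtracting one channel from another.

    Any channel can serve as the reference after the fact; the bipolar
    signal is the elementwise difference measurement - reference.
    """
    meas = rec.channel(measurement)
    ref = rec.channel(reference)
    return BipolarSignal(
        samples=meas - ref,
        fs=rec.fs,
        measurement_label=measurement,
        reference_label=reference,
    )


def traditional_pair(
    rec: MultichannelRecording, left_offset_cm: float = 4.0
) -> tuple[str, str]:
    """Pick the conventional single-pair EGG montage from the layout.

    The reference is the electrode nearest the midline origin (halfway
    between xiphoid process and umbilicus); the measurement is the
    electrode nearest ``left_offset_cm`` toward the subject's left of the
    reference.  Returns ``(measurement_label, reference_label)``.
    """
    if rec.layout is None:
        raise ValueError("recording has no electrode layout; cannot locate the traditional pair")
    if rec.n_channels < 2:
        raise ValueError("need at least two channels for a bipolar pair")
    labels = list(rec.channel_labels)
    pos = np.array([rec.layout[c] for c in labels], dtype=float)

    # one grid spacing = smallest inter-electrode distance
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    spacing = float(np.sqrt(d2.min()))

    def nearest(target: np.ndarray, exclude: int | None = None) -> int:
        dist = np.linalg.norm(pos - target, axis=1)
        if exclude is not None:
            dist[exclude] = np.inf
        idx = int(np.argmin(dist))
        if dist[idx] > spacing + 1e-9:
            warnings.warn(
                f"no electrode within one grid spacing of {tuple(target)}; "
                f"using best match {labels[idx]!r}",
                stacklevel=3,
            )
        return idx

    ref_idx = nearest(np.zeros(2))
    target = pos[ref_idx] + np.array([left_offset_cm, 0.0])
    meas_idx = nearest(target, exclude=ref_idx)
    return labels[meas_idx], labels[ref_idx]
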