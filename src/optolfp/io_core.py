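"""Domain types and file I/O for two-channel LFP sessions.

A session is a 3-h recording (pre hour, light-ON hour, post hour) from two
hippocampal depth electrodes.  Signals travel as 16-bit EDF (one data record
per second, physical unit mV); discrete events (light pulses, generalized
seizures, ground-truth annotations) travel as a plain CSV with columns
``label,onset_s,duration_s``.

Conventions used throughout the package:

* time is float seconds from recording start;
* every interval is half-open ``[a, b)``;
* sample ``i`` covers ``[i/fs, (i+1)/fs)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EventList",
    "PulseSchedule",
    "SessionLayout",
    "Recording",
    "expected_pulse_times",
    "read_recording",
    "write_recording",
    "read_edf",
    "write_edf",
]

EVENT_COLUMNS = ("label", "onset_s", "duration_s")

#: channel label sets accepted for the two electrode placements
CHANNEL_SETS = (("HCi", "HCc"), ("left", "right"))

GROUPS = ("PACK", "bPAC", "mCherry", "no_virus")
TREATMENTS = ("saline", "kainate")
SESSIONS = ("ref", "stim_0.05", "stim_0.1")


class ValidationError(ValueError):
    """An object violates one of its documented invariants."""


class FormatError(IOError):
    """A file on disk does not match the expected container format."""


# ---------------------------------------------------------------------------
# event lists
# ---------------------------------------------------------------------------

@dataclass
class EventList:
    """Sorted list of labelled intervals ``(label, onset_s, duration_s)``."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=list(EVENT_COLUMNS))
    )

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in EVENT_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"event table missing columns {missing}")
        t = t.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        t["onset_s"] = t["onset_s"].astype(float)
        t["duration_s"] = t["duration_s"].astype(float)
        if len(t):
            if (t["onset_s"] < 0).any():
                raise ValidationError("event onset < 0")
            if (t["duration_s"] < 0).any():
                raise ValidationError("event duration < 0")
            if not t["onset_s"].is_monotonic_increasing:
                raise ValidationError("events not sorted by onset")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_records(cls, records) -> "EventList":
        df = pd.DataFrame(records, columns=list(EVENT_COLUMNS))
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
        return cls(df)

    def with_event(self, label: str, onset_s: float, duration_s: float) -> "EventList":
        df = pd.concat(
            [self.table, pd.DataFrame([[label, onset_s, duration_s]],
                                      columns=list(EVENT_COLUMNS))],
            ignore_index=True,
        )
        df = df.sort_values("onset_s", kind="stable").reset_index(drop=True)
        return EventList(df)

    def intervals(self, labels) -> np.ndarray:
        """Return ``(n, 2)`` array of [onset, end) intervals for ``labels``."""
        if isinstance(labels, str):
            labels = [labels]
        sel = self.table[self.table["label"].isin(labels)]
        out = np.column_stack(
            [sel["onset_s"].to_numpy(), sel["onset_s"].to_numpy() + sel["duration_s"].to_numpy()]
        ) if len(sel) else np.empty((0, 2))
        return out

    def labels(self) -> set:
        return set(self.table["label"])


# ---------------------------------------------------------------------------
# illumination protocol and session layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSchedule:
    """Intermittent illumination protocol.

    10-ms pulses (with a 5-ms ramped termination to avoid rebound
    excitation) delivered every 10 s (0.1 Hz) or 20 s (0.05 Hz) during the
    light-ON hour; during the final ``fadeoff_tail`` seconds light intensity
    fades out, so that tail is excluded from analysis.
    """

    frequency: float
    pulse_width: float = 0.010
    ramp: float = 0.005
    light_on: tuple = (3600.0, 7200.0)
    fadeoff_tail: float = 600.0

    def __post_init__(self) -> None:
        t0, t1 = self.light_on
        if self.frequency <= 0:
            raise ValidationError("pulse frequency must be > 0")
        if self.pulse_width >= 1.0 / self.frequency:
            raise ValidationError("pulse_width must be shorter than the pulse period")
        if not (t1 > t0 and t1 - t0 > self.fadeoff_tail >= 0):
            raise ValidationError("light_on window shorter than fade-off tail")

    @property
    def analysis_window(self) -> tuple:
        """Light-ON window with the intensity fade-off tail removed."""
        t0, t1 = self.light_on
        return (t0, t1 - self.fadeoff_tail)


def expected_pulse_times(schedule: PulseSchedule) -> np.ndarray:
    """Pulse onsets ``t0, t0 + 1/f, ...`` strictly inside ``[t0, t1)``."""
    t0, t1 = schedule.light_on
    period = 1.0 / schedule.frequency
    n = int(np.floor((t1 - t0) / period - 1e-9)) + 1
    return t0 + period * np.arange(n)


@dataclass(frozen=True)
class SessionLayout:
    """Hour boundaries of a session, scalable for small test problems.

    ``hour_s`` is the nominal hour (3600 s at study scale); ``fadeoff_s`` is
    the light-intensity fade-off tail dropped from the light-ON hour when
    analysing stimulation sessions.
    """

    hour_s: float = 3600.0
    fadeoff_s: float = 600.0
    n_hours: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.fadeoff_s < self.hour_s):
            raise ValidationError("fade-off tail must be within one hour")
        if self.n_hours < 3:
            raise ValidationError("a session has at least pre/light/post hours")

    @property
    def total_s(self) -> float:
        return self.n_hours * self.hour_s

    @property
    def pre(self) -> tuple:
        return (0.0, self.hour_s)

    @property
    def light_on(self) -> tuple:
        return (self.hour_s, 2 * self.hour_s)

    @property
    def light_analysis(self) -> tuple:
        return (self.hour_s, 2 * self.hour_s - self.fadeoff_s)

    @property
    def post(self) -> tuple:
        return (2 * self.hour_s, 3 * self.hour_s)

    def hour(self, i: int) -> tuple:
        """Half-open interval of hour ``i`` (1-based)."""
        if not 1 <= i <= self.n_hours:
            raise ValidationError(f"hour index {i} out of range")
        return ((i - 1) * self.hour_s, i * self.hour_s)

    def default_schedule(self, frequency: float) -> PulseSchedule:
        return PulseSchedule(frequency=frequency, light_on=self.light_on,
                             fadeoff_tail=self.fadeoff_s)


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """A multi-channel LFP session with events and metadata.

    ``data`` is shaped ``(n_channels, n_samples)`` in mV.  ``pulses`` is
    either an explicit onset array (s) or a :class:`PulseSchedule`.
    """

    labels: list
    data: np.ndarray
    fs: float
    pulses: object = None
    annotations: EventList = field(default_factory=EventList)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if self.fs <= 0:
            raise ValidationError("fs must be > 0")
        if self.data.ndim != 2 or self.data.shape[0] == 0:
            raise ValidationError("recording needs at least one channel")
        if len(self.labels) != self.data.shape[0]:
            raise ValidationError("channel label count != channel count")
        onsets = self.pulse_onsets()
        if onsets.size:
            if np.any(np.diff(onsets) <= 0):
                raise ValidationError("pulse onsets not strictly increasing")
            if onsets[0] < 0 or onsets[-1] >= self.duration:
                raise ValidationError("pulse onset outside recording")
        ev = self.annotations.table
        if len(ev):
            if ((ev["onset_s"] >= self.duration) | (ev["onset_s"] < 0)).any():
                raise ValidationError("annotation onset outside recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def pulse_onsets(self) -> np.ndarray:
        if self.pulses is None:
            return np.empty(0)
        if isinstance(self.pulses, PulseSchedule):
            return expected_pulse_times(self.pulses)
        return np.asarray(self.pulses, dtype=float)

    def channel(self, label: str) -> np.ndarray:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel labelled {label!r}") from None
        return self.data[i]

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data)


# ---------------------------------------------------------------------------
# minimal EDF container (16-bit, one data record per second)
# ---------------------------------------------------------------------------
# The EDF header is plain ASCII: a 256-byte global block followed by one
# 256-byte block worth of per-signal fields; samples are little-endian
# int16, channel-blocked within each 1-s data record.

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _fmt_num(value: float, width: int = 8) -> str:
    for prec in range(7, -1, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return s
    raise FormatError(f"cannot format {value} in {width} chars")


def write_edf(path, data: np.ndarray, fs: float, labels,
              phys_max: float | None = None) -> Path:
    """Write ``(n_ch, n)`` mV data as a 16-bit EDF with 1-s data records.

    The physical range is symmetric ``[-R, R]``; by default ``R`` is 10 mV,
    enlarged to the next integer mV if the data exceed it.  Quantization
    error is therefore at most ``R / 32768`` mV per sample.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_ch, n = data.shape
    if n_ch == 0 or n == 0:
        raise ValidationError("cannot write an empty recording")
    fs_i = int(round(fs))
    if abs(fs - fs_i) > 1e-9:
        raise ValidationError("EDF container requires an integer sampling rate")
    if n % fs_i:
        raise ValidationError("EDF container requires a whole number of seconds")
    n_rec = n // fs_i
    if phys_max is None:
        peak = float(np.max(np.abs(data))) if data.size else 0.0
        phys_max = max(10.0, float(np.ceil(peak * 1.0001)))
    R = float(phys_max)

    dig_min, dig_max = -32768, 32767
    scale = 2 * R / (dig_max - dig_min)
    dig = np.round((data + R) / scale).astype(np.int64) + dig_min
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),               # patient
        _pad("Startdate X X X X", 80),     # recording
        _pad("01.01.01", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + n_ch)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),                      # record duration, s
        _pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_pad(str(lbl), 16) for lbl in labels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in labels),
        b"".join(_pad("mV", 8) for _ in labels),
        b"".join(_pad(_fmt_num(-R), 8) for _ in labels),
        b"".join(_pad(_fmt_num(R), 8) for _ in labels),
        b"".join(_pad(str(dig_min), 8) for _ in labels),
        b"".join(_pad(str(dig_max), 8) for _ in labels),
        b"".join(_pad("", 80) for _ in labels),
        b"".join(_pad(str(fs_i), 8) for _ in labels),
        b"".join(_pad("", 32) for _ in labels),
    ])
    # records: channel-blocked samples per 1-s record
    body = (
        dig.reshape(n_ch, n_rec, fs_i)
        .transpose(1, 0, 2)
        .tobytes()
    )
    path = Path(path)
    path.write_bytes(header + sig + body)
    return path


def read_edf(path):
    """Read an EDF written by :func:`write_edf` (or compatible).

    Returns ``(data_mV, fs, labels)``.
    """
    path = Path(path)
    try:
        raw = path.read_bytes()
    except OSError as exc:
        raise IOError(f"cannot read EDF file {path}: {exc}") from exc
    if len(raw) < 256:
        raise FormatError(f"{path}: truncated EDF header")
    try:
        n_rec = int(raw[236:244].decode("ascii").strip())
        rec_dur = float(raw[244:252].decode("ascii").strip())
        n_ch = int(raw[252:256].decode("ascii").strip())
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header") from exc
    off = 256

    def field_block(width):
        nonlocal off
        vals = [raw[off + i * width: off + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)]
        off += n_ch * width
        return vals

    labels = field_block(16)
    field_block(80)                      # transducer
    units = field_block(8)
    pmin = [float(v) for v in field_block(8)]
    pmax = [float(v) for v in field_block(8)]
    dmin = [int(v) for v in field_block(8)]
    dmax = [int(v) for v in field_block(8)]
    field_block(80)                      # prefiltering
    spr = [int(v) for v in field_block(8)]
    field_block(32)

    if len(set(spr)) != 1:
        raise FormatError(f"{path}: channels disagree on samples per record")
    fs = spr[0] / rec_dur
    header_bytes = 256 * (1 + n_ch)
    expected = header_bytes + n_rec * sum(spr) * 2
    if len(raw) < expected:
        raise FormatError(f"{path}: EDF body shorter than header promises")
    body = np.frombuffer(raw[header_bytes:expected], dtype="<i2")
    body = body.reshape(n_rec, n_ch, spr[0]).transpose(1, 0, 2).reshape(n_ch, -1)
    data = np.empty(body.shape, dtype=float)
    for c in range(n_ch):
        scale = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
        data[c] = (body[c].astype(float) - dmin[c]) * scale + pmin[c]
        if units[c] not in ("mV", "uV"):
            raise FormatError(f"{path}: unexpected physical unit {units[c]!r}")
        if units[c] == "uV":
            data[c] /= 1000.0
    return data, fs, labels


# ---------------------------------------------------------------------------
# recording-level I/O
# ---------------------------------------------------------------------------

def read_recording(signal_path, events_path, meta: dict | None = None,
                   expected_channels: int | None = 2) -> Recording:
    """Load a session from an EDF signal file and an events CSV.

    Rows labelled ``pulse`` in the events file become the pulse-onset list;
    all other rows become annotations (``GS`` marks generalized seizures).
    """
    data, fs, labels = read_edf(signal_path)
    if expected_channels is not None and data.shape[0] != expected_channels:
        raise FormatError(
            f"{signal_path}: expected {expected_channels} channels, found {data.shape[0]}"
        )
    try:
        ev = pd.read_csv(events_path)
    except OSError as exc:
        raise IOError(f"cannot read events file {events_path}: {exc}") from exc
    if list(ev.columns) != list(EVENT_COLUMNS):
        raise FormatError(
            f"{events_path}: expected header {','.join(EVENT_COLUMNS)}"
        )
    pulses = ev[ev["label"] == "pulse"]["onset_s"].to_numpy(dtype=float)
    rest = ev[ev["label"] != "pulse"].reset_index(drop=True)
    return Recording(
        labels=labels,
        data=data,
        fs=fs,
        pulses=pulses if pulses.size else None,
        annotations=EventList(rest),
        meta=dict(meta or {}),
    )


def write_recording(recording: Recording, signal_path, events_path,
                    phys_max: float | None = None):
    """Write a session as EDF + events CSV; inverse of :func:`read_recording`
    up to 16-bit quantization of the samples."""
    recording.validate()
    write_edf(signal_path, recording.data, recording.fs, recording.labels,
              phys_max=phys_max)
    onsets = recording.pulse_onsets()
    width = (recording.pulses.pulse_width
             if isinstance(recording.pulses, PulseSchedule) else 0.0)
    pulse_df = pd.DataFrame({
        "label": "pulse",
        "onset_s": onsets,
        "duration_s": np.full(onsets.size, width),
    })
    ev = pd.concat([pulse_df, recording.annotations.table], ignore_index=True)
    ev = ev.sort_values("onset_s", kind="stable").reset_index(drop=True)
    ev.to_csv(events_path, index=False)
    return Path(signal_path), Path(events_path)
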