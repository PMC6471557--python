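"""Data containers and on-disk formats.

Recordings travel as European Data Format (EDF) files with one 1-s data
record per second and physical units of µV; event tables travel as
tab-separated text with columns ``onset  duration  stimulus  condition``
(onset in seconds, 6-decimal fixed point).  Readers validate rather than
silently coerce: malformed headers, unit mismatches and non-monotone event
onsets are hard errors naming the offending field or row.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .config import STIMULI

__all__ = [
    "Recording",
    "EventStream",
    "EpochSet",
    "IOValidationError",
    "read_edf",
    "write_edf",
    "read_events",
    "write_events",
    "validate_channels",
]


class IOValidationError(ValueError):
    """Raised when a file fails schema or consistency validation."""


@dataclass
class Recording:
    """Continuous multichannel EEG: ``data`` is (channels × samples) in µV."""

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels × samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, self.channel_names, dict(self.meta))


@dataclass
class EventStream:
    """Ordered oddball stimulus onsets with stimulus label and condition."""

    onset: np.ndarray  # seconds from recording start
    stimulus: np.ndarray  # 'target' | 'standard'
    condition: np.ndarray  # 'low' | 'high'
    duration: np.ndarray | None = None

    def __post_init__(self):
        self.onset = np.asarray(self.onset, dtype=float)
        self.stimulus = np.asarray(self.stimulus, dtype=object)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.duration is None:
            self.duration = np.zeros_like(self.onset)
        else:
            self.duration = np.asarray(self.duration, dtype=float)
        n = len(self.onset)
        if not (len(self.stimulus) == len(self.condition) == len(self.duration) == n):
            raise ValueError("event columns have unequal lengths")
        if n > 1 and not np.all(np.diff(self.onset) > 0):
            bad = int(np.flatnonzero(np.diff(self.onset) <= 0)[0]) + 1
            raise IOValidationError(
                f"event onsets must be strictly increasing (row {bad}, "
                f"onset {self.onset[bad]:.6f} after {self.onset[bad - 1]:.6f})"
            )
        unknown = set(self.stimulus) - set(STIMULI)
        if unknown:
            raise IOValidationError(f"unknown stimulus labels: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.onset)

    def select(self, stimulus: str | None = None) -> "EventStream":
        if stimulus is None:
            return self
        mask = self.stimulus == stimulus
        return EventStream(
            self.onset[mask], self.stimulus[mask], self.condition[mask],
            self.duration[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": self.onset,
                "duration": self.duration,
                "stimulus": self.stimulus,
                "condition": self.condition,
            }
        )


@dataclass
class EpochSet:
    """Fixed-length trials: ``data`` is (epochs × channels × samples) in µV.

    The sample grid is half-open ``[tmin, tmax)``: an epoch from −0.2 to
    +1.0 s at 500 Hz has exactly 600 samples.
    """

    data: np.ndarray
    tmin: float
    fs: float
    channel_names: tuple[str, ...]
    metadata: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs × channels × samples)")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata length must equal epoch count")
        if "retained" not in self.metadata.columns:
            self.metadata = self.metadata.assign(retained=True)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def tmax(self) -> float:
        return self.tmin + self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channel_names}") from None

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.tmin, self.fs, self.channel_names,
            self.metadata.copy(), self.n_dropped,
        )

    def subset(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.data[mask], self.tmin, self.fs, self.channel_names,
            self.metadata.iloc[mask].reset_index(drop=True), self.n_dropped,
        )


# --------------------------------------------------------------------------
# EDF (European Data Format), 16-bit integer encoding, 1-s data records.

_EDF_UNIT = "uV"


def _pad_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise IOValidationError(f"EDF header field {value!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def _num_field(value: float, width: int) -> bytes:
    for fmt in (f"{value:.{width - 2}g}", f"{value:.0f}"):
        s = fmt
        if len(s) <= width:
            return s.ljust(width).encode("ascii")
    raise IOValidationError(f"cannot encode {value} in {width} EDF bytes")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF, one data record per second.

    The physical range is the symmetric per-file amplitude extreme, so the
    quantization step is ``physical_range / 2**15``.  The last data record
    is zero-padded when the recording length is not a whole number of
    seconds.
    """
    path = Path(path)
    fs = recording.fs
    spr = int(round(fs))  # samples per 1-s record per signal
    if abs(fs - spr) > 1e-9:
        raise IOValidationError(f"EDF writer requires an integer fs, got {fs}")
    n_ch = recording.n_channels
    n = recording.n_samples
    n_records = int(np.ceil(n / spr)) if n else 0

    pmax = float(np.max(np.abs(recording.data))) if n else 1.0
    if pmax == 0:
        pmax = 1.0
    dig_max = 32767

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad_field("0", 8),
            _pad_field("X X X X", 80),
            _pad_field("Startdate X X X X", 80),
            _pad_field(now.strftime("%d.%m.%y"), 8),
            _pad_field(now.strftime("%H.%M.%S"), 8),
            _pad_field(256 * (1 + n_ch), 8),
            _pad_field("", 44),
            _pad_field(n_records, 8),
            _pad_field("1", 8),  # record duration, seconds
            _pad_field(n_ch, 4),
        ]
    )
    labels = b"".join(_pad_field(ch, 16) for ch in recording.channel_names)
    transducer = b"".join(_pad_field("", 80) for _ in range(n_ch))
    phys_dim = b"".join(_pad_field(_EDF_UNIT, 8) for _ in range(n_ch))
    phys_min = b"".join(_num_field(-pmax, 8) for _ in range(n_ch))
    phys_max = b"".join(_num_field(pmax, 8) for _ in range(n_ch))
    dig_min = b"".join(_pad_field(-dig_max, 8) for _ in range(n_ch))
    dig_max_b = b"".join(_pad_field(dig_max, 8) for _ in range(n_ch))
    prefilter = b"".join(_pad_field("", 80) for _ in range(n_ch))
    spr_b = b"".join(_pad_field(spr, 8) for _ in range(n_ch))
    reserved = b"".join(_pad_field("", 32) for _ in range(n_ch))

    # re-read the physical extremes as written, so scaling matches the file
    pmin_w = float(_num_field(-pmax, 8).decode())
    pmax_w = float(_num_field(pmax, 8).decode())
    scale = (2 * dig_max) / (pmax_w - pmin_w)

    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n] = recording.data
    digital = np.clip(np.rint(padded * scale), -dig_max, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(labels + transducer + phys_dim + phys_min + phys_max)
        fh.write(dig_min + dig_max_b + prefilter + spr_b + reserved)
        for rec in range(n_records):
            chunk = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(chunk.tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read a 16-bit EDF file written by :func:`write_edf` (or compatible)."""
    path = Path(path)
    if not path.exists():
        raise IOValidationError(f"EDF file not found: {path}")
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise IOValidationError("EDF header truncated (field: fixed header)")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_dur = float(head[244:252].decode("ascii").strip())
            n_ch = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise IOValidationError(f"malformed EDF fixed header: {exc}") from None
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise IOValidationError("EDF header truncated (field: signal headers)")

        def col(offset: int, width: int) -> list[str]:
            base = offset * n_ch
            return [
                sig[base + i * width : base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)
            ]

        labels = col(0, 16)
        phys_dim = col(96, 8)
        try:
            phys_min = [float(v) for v in col(104, 8)]
            phys_max = [float(v) for v in col(112, 8)]
            dig_min = [int(v) for v in col(120, 8)]
            dig_max = [int(v) for v in col(128, 8)]
            spr = [int(v) for v in col(216, 8)]
        except ValueError as exc:
            raise IOValidationError(f"malformed EDF signal header: {exc}") from None

        bad_unit = [f"{l}={d!r}" for l, d in zip(labels, phys_dim) if d != _EDF_UNIT]
        if bad_unit:
            raise IOValidationError(
                f"physical dimension mismatch (expected {_EDF_UNIT!r}): "
                + ", ".join(bad_unit)
            )
        if len(set(spr)) != 1:
            raise IOValidationError("per-signal sampling rates differ (field: spr)")
        fs = spr[0] / record_dur

        data = np.empty((n_ch, n_records * spr[0]))
        rec_len = sum(spr)
        for rec in range(n_records):
            raw = fh.read(2 * rec_len)
            if len(raw) < 2 * rec_len:
                raise IOValidationError(f"EDF data record {rec} truncated")
            block = np.frombuffer(raw, dtype="<i2").reshape(n_ch, spr[0])
            data[:, rec * spr[0] : (rec + 1) * spr[0]] = block
    for i in range(n_ch):
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        data[i] = (data[i] - dig_min[i]) * gain + phys_min[i]
    return Recording(data, fs, tuple(labels), meta={"source": str(path)})


def validate_channels(recording: Recording, expected: tuple[str, ...]) -> None:
    """Reject a recording missing any of the pipeline's expected channels."""
    missing = [ch for ch in expected if ch not in recording.channel_names]
    if missing:
        raise IOValidationError(
            f"recording is missing expected channels: {missing} "
            f"(found {list(recording.channel_names)})"
        )


# --------------------------------------------------------------------------
# Tab-separated event tables.

_EVENT_COLUMNS = ["onset", "duration", "stimulus", "condition"]


def write_events(events: EventStream, path: str | Path) -> None:
    df = events.to_frame()
    df["onset"] = df["onset"].map(lambda v: f"{v:.6f}")
    df["duration"] = df["duration"].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> EventStream:
    path = Path(path)
    if not path.exists():
        raise IOValidationError(f"events file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"stimulus": str, "condition": str})
    missing = [c for c in _EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise IOValidationError(f"events file missing columns: {missing}")
    if len(df) == 0:
        return EventStream(
            np.empty(0), np.empty(0, object), np.empty(0, object), np.empty(0)
        )
    return EventStream(
        df["onset"].to_numpy(float),
        df["stimulus"].to_numpy(object),
        df["condition"].to_numpy(object),
        df["duration"].to_numpy(float),
    )
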