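"""Recording data model and canonical on-disk format.

A recording is a 1 Hz multichannel electrochemical time series with a
per-timestamp beverage label and session/cycle metadata.  The canonical
on-disk representation is a flat CSV with the header

    time_s,session,cycle,label,TEMP,ISF1,ISF2,ISF3,ISF4,ISF5,ISF6,COND,ORP

(channel columns restricted to whatever subset the recording carries).
Timestamps are integer seconds on the 1 Hz grid; gaps encode removed or
invalid periods.  Labels are integers 0–4 for the five beverages and the
sentinel -1 for the discarded non-beverage (wash/transfer) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical channel order of the nine-sensor array: temperature, the six
#: ion-sensitive FETs (pH, K+, Na+, Cl-, NO3-, Ca2+), conductivity, redox.
CHANNELS: tuple[str, ...] = (
    "TEMP", "ISF1", "ISF2", "ISF3", "ISF4", "ISF5", "ISF6", "COND", "ORP",
)

#: Beverage label codes.
BEVERAGES: dict[int, str] = {
    0: "white wine",
    1: "red wine",
    2: "still water",
    3: "sparkling water",
    4: "cava",
}

#: Sentinel label for wash/transfer periods, discarded before sampling.
NON_BEVERAGE: int = -1

_META_COLUMNS = ("time_s", "session", "cycle", "label")


class RecordingFormatError(ValueError):
    """Raised when an on-disk recording violates the canonical format."""


class RecordingValidationError(ValueError):
    """Raised when recording contents violate the data-model invariants."""


@dataclass
class RawRecording:
    """Timestamped multichannel sensor series with per-timestamp labels.

    Parameters
    ----------
    timestamps : integer seconds, strictly increasing within each session
    values : float matrix ``[n_measurements, n_channels]`` in physical units
    labels : integer labels in ``{-1, 0, .., 4}`` per measurement
    session : session id (>= 1) per measurement
    cycle : measurement-cycle index within the session, per measurement
    channels : ordered channel names, a subset of :data:`CHANNELS`
    """

    timestamps: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    session: np.ndarray
    cycle: np.ndarray
    channels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.session = np.asarray(self.session, dtype=np.int64)
        self.cycle = np.asarray(self.cycle, dtype=np.int64)
        self.channels = tuple(self.channels)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n = len(self.timestamps)
        if self.values.shape != (n, len(self.channels)) and not (n == 0 and self.values.size == 0):
            raise RecordingValidationError(
                f"values shape {self.values.shape} does not match "
                f"{n} measurements x {len(self.channels)} channels"
            )
        for arr, name in ((self.labels, "labels"), (self.session, "session"), (self.cycle, "cycle")):
            if arr.shape != (n,):
                raise RecordingValidationError(f"{name} has length {arr.shape}, expected {n}")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise RecordingFormatError(f"unknown channels: {sorted(unknown)}")
        if len(set(self.channels)) != len(self.channels):
            raise RecordingFormatError("duplicate channels")
        if n and not np.isfinite(self.values).all():
            raise RecordingValidationError("non-finite sensor values")
        bad = ~np.isin(self.labels, [-1, 0, 1, 2, 3, 4])
        if bad.any():
            raise RecordingValidationError(f"labels outside -1..4: {np.unique(self.labels[bad])}")
        if n and (self.session < 1).any():
            raise RecordingValidationError("session ids must be >= 1")
        for sid in np.unique(self.session):
            ts = self.timestamps[self.session == sid]
            if np.any(np.diff(ts) <= 0):
                raise RecordingValidationError(
                    f"timestamps not strictly increasing within session {sid}"
                )

    # -- convenience ---------------------------------------------------
    @property
    def n_measurements(self) -> int:
        return len(self.timestamps)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "time_s": self.timestamps,
                "session": self.session,
                "cycle": self.cycle,
                "label": self.labels,
            }
        )
        for j, ch in enumerate(self.channels):
            df[ch] = self.values[:, j] if self.n_measurements else np.empty(0)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channels: tuple[str, ...] | None = None) -> "RawRecording":
        missing = [c for c in _META_COLUMNS if c not in df.columns]
        if missing:
            raise RecordingFormatError(f"missing columns: {missing}")
        if channels is None:
            channels = tuple(c for c in df.columns if c not in _META_COLUMNS)
        absent = [c for c in channels if c not in df.columns]
        if absent:
            raise RecordingFormatError(f"missing channel columns: {absent}")
        df = df.sort_values(["session", "time_s"], kind="stable")
        vals = df[list(channels)].to_numpy(dtype=np.float64)
        if len(df) == 0:
            vals = np.empty((0, len(channels)))
        return cls(
            timestamps=df["time_s"].to_numpy(),
            values=vals,
            labels=df["label"].to_numpy(),
            session=df["session"].to_numpy(),
            cycle=df["cycle"].to_numpy(),
            channels=channels,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return (
            self.channels == other.channels
            and np.array_equal(self.timestamps, other.timestamps)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.labels, other.labels)
            and np.array_equal(self.session, other.session)
            and np.array_equal(self.cycle, other.cycle)
        )


def write_recording(rec: RawRecording, path) -> str:
    """Write a recording to the canonical CSV dialect.

    Floats are written with ``repr`` round-trip precision so that
    ``read_recording(write_recording(rec)) == rec`` bit for bit.
    """
    df = rec.to_frame()
    df.to_csv(path, index=False, float_format=None)
    return str(path)


def read_recording(path, format: str = "canonical-csv") -> RawRecording:
    """Read a recording from disk.

    Parameters
    ----------
    path : file path
    format : ``"canonical-csv"`` for the native dialect, or
        ``"zenodo-adapter"`` to route through :func:`adapt_external`.
    """
    if format == "canonical-csv":
        df = pd.read_csv(path, float_precision="round_trip")
        return RawRecording.from_frame(df)
    if format == "zenodo-adapter":
        return adapt_external(path)
    raise RecordingFormatError(f"unknown format {format!r}")


#: Column aliases accepted by the external-dump adapter, mapping
#: lower-cased external names onto the canonical schema.
_EXTERNAL_ALIASES = {
    "time": "time_s",
    "timestamp": "time_s",
    "t": "time_s",
    "time_s": "time_s",
    "session": "session",
    "session_id": "session",
    "day": "session",
    "cycle": "cycle",
    "cycle_id": "cycle",
    "label": "label",
    "class": "label",
    "beverage": "label",
    "temp": "TEMP",
    "temperature": "TEMP",
    "cond": "COND",
    "conductivity": "COND",
    "orp": "ORP",
    "isf1": "ISF1", "isf2": "ISF2", "isf3": "ISF3",
    "isf4": "ISF4", "isf5": "ISF5", "isf6": "ISF6",
    "ph": "ISF1", "k": "ISF2", "na": "ISF3",
    "cl": "ISF4", "no3": "ISF5", "ca": "ISF6",
}


def adapt_external(path, column_map: dict[str, str] | None = None) -> RawRecording:
    """Adapt an external wide-CSV dump (e.g. a public deposit) to the model.

    The adapter renames columns via ``column_map`` (external name ->
    canonical name) merged over a set of common aliases, fills a missing
    ``cycle`` column with 0 and a missing ``session`` with 1, and validates
    the result.  It deliberately concentrates all format risk for external
    layouts in this one function; dumps that do not fit a flat wide table
    must be converted upstream.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    rename: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if column_map and col in column_map:
            rename[col] = column_map[col]
        elif key in _EXTERNAL_ALIASES:
            rename[col] = _EXTERNAL_ALIASES[key]
    df = df.rename(columns=rename)
    if "session" not in df.columns:
        df["session"] = 1
    if "cycle" not in df.columns:
        df["cycle"] = 0
    if "time_s" not in df.columns:
        raise RecordingFormatError("adapter could not locate a timestamp column")
    if "label" not in df.columns:
        raise RecordingFormatError("adapter could not locate a label column")
    channels = tuple(c for c in CHANNELS if c in df.columns)
    if not channels:
        raise RecordingFormatError("adapter found no recognizable sensor channels")
    return RawRecording.from_frame(df[[*_META_COLUMNS, *channels]], channels=channels)


def select_channels(rec: RawRecording, channels) -> RawRecording:
    """Restrict and reorder a recording's columns to ``channels``.

    Labels, timestamps and metadata are untouched.  Requested channels must
    be a subset of the recording's channels.
    """
    channels = tuple(channels)
    unknown = [c for c in channels if c not in rec.channels]
    if unknown:
        raise RecordingFormatError(f"channels not in recording: {unknown}")
    idx = [rec.channels.index(c) for c in channels]
    vals = rec.values[:, idx] if rec.n_measurements else np.empty((0, len(channels)))
    return RawRecording(
        timestamps=rec.timestamps,
        values=vals,
        labels=rec.labels,
        session=rec.session,
        cycle=rec.cycle,
        channels=channels,
    )
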