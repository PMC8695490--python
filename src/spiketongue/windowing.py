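"""Sliding-window sample generation and the chronological train/test split.

A sample is a ``T x N`` window that slides with stride 1 over the stored
(preprocessed) row sequence.  A window is kept only if all ``T`` of its
measurements carry the same beverage label; its label is the label of the
latest measurement.  Windows never span session boundaries.  The test set
is the last complete measurement cycle of the final session, so no test
measurement precedes any training measurement of the same cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import warnings

import numpy as np

from spiketongue.dataio import RawRecording

DEFAULT_WINDOW = 16


@dataclass
class WindowSet:
    """Array of labeled ``T x N`` windows with provenance.

    ``samples[i]`` holds ``T`` consecutive stored rows ending at
    ``end_timestamps[i]`` in session ``session[i]``, cycle ``cycle[i]``;
    consecutive windows from the same run share ``T - 1`` rows.
    """

    samples: np.ndarray          # [n_samples, T, N]
    labels: np.ndarray           # [n_samples]
    end_timestamps: np.ndarray   # [n_samples]
    session: np.ndarray          # [n_samples]
    cycle: np.ndarray            # [n_samples]
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def T(self) -> int:
        return self.samples.shape[1]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[2]

    def flat(self) -> np.ndarray:
        """Windows flattened to ``[n_samples, T * N]`` feature vectors."""
        return self.samples.reshape(len(self), -1)

    def subset(self, mask: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.samples[mask], self.labels[mask], self.end_timestamps[mask],
            self.session[mask], self.cycle[mask], self.channels,
        )

    def save(self, prefix) -> None:
        """Serialize to ``<prefix>.npy`` plus a JSON sidecar."""
        np.save(f"{prefix}.npy", self.samples)
        sidecar = {
            "T": int(self.T), "channels": list(self.channels),
            "labels": self.labels.tolist(),
            "end_timestamps": np.asarray(self.end_timestamps).tolist(),
            "session": np.asarray(self.session).tolist(),
            "cycle": np.asarray(self.cycle).tolist(),
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load(cls, prefix) -> "WindowSet":
        samples = np.load(f"{prefix}.npy")
        with open(f"{prefix}.json") as fh:
            sc = json.load(fh)
        return cls(
            samples, np.asarray(sc["labels"]), np.asarray(sc["end_timestamps"]),
            np.asarray(sc["session"]), np.asarray(sc["cycle"]), tuple(sc["channels"]),
        )


def label_runs(labels: np.ndarray, session: np.ndarray) -> list[np.ndarray]:
    """Maximal stretches of stored rows with constant (session, label)."""
    n = len(labels)
    if n == 0:
        return []
    breaks = np.flatnonzero((np.diff(labels) != 0) | (np.diff(session) != 0)) + 1
    return np.split(np.arange(n), breaks)


def make_windows(rec: RawRecording, T: int = DEFAULT_WINDOW) -> WindowSet:
    """Build all single-label stride-1 windows of length ``T``.

    Rows separated by removed data remain adjacent in stored order; only
    windows whose rows span multiple labels (or sessions) are discarded.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    idx_list = []
    for run in label_runs(rec.labels, rec.session):
        if len(run) >= T:
            starts = run[: len(run) - T + 1]
            idx_list.append(starts[:, None] + np.arange(T))
    if not idx_list:
        warnings.warn(f"no labeled run of length >= {T}; empty window set")
        return WindowSet(
            np.empty((0, T, rec.n_channels)), np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.int64), rec.channels,
        )
    idx = np.concatenate(idx_list)
    ends = idx[:, -1]
    return WindowSet(
        samples=rec.values[idx],
        labels=rec.labels[ends],
        end_timestamps=rec.timestamps[ends],
        session=rec.session[ends],
        cycle=rec.cycle[ends],
        channels=rec.channels,
    )


def count_windows_oracle(labels, T: int) -> int:
    """Brute-force window count: slide over every position and keep the
    single-label ones.  Independent of :func:`make_windows`."""
    labels = list(labels)
    return sum(
        1
        for i in range(len(labels) - T + 1)
        if len(set(labels[i:i + T])) == 1
    )


def split_train_test(ws: WindowSet, rec: RawRecording) -> tuple[WindowSet, WindowSet]:
    """Chronological split: last complete cycle of the final session is test.

    Windows whose end row falls in that cycle form the test set; all other
    windows train.  Single-label windows cannot straddle the cycle
    boundary because consecutive segments always change beverage.
    """
    if rec.n_measurements == 0:
        raise ValueError("empty recording: no complete cycle available")
    last_session = rec.session.max()
    last_cycle = rec.cycle[rec.session == last_session].max()
    is_test = (ws.session == last_session) & (ws.cycle == last_cycle)
    if not is_test.any():
        raise ValueError("no windows in the final session's last cycle")
    return ws.subset(~is_test), ws.subset(is_test)
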