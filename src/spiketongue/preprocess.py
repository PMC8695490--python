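"""Per-session preprocessing: balancing, high-pass filtering, outlier
removal and quantile normalization.

Each recording session is filtered and normalized independently because
sensor offsets and sensitivities change between sessions (including
discrete sensor replacements).  The pipeline order is fixed:

    balance_cycles -> highpass_filter (per channel) ->
    remove_outliers (train statistics) -> apply_quantile_map (train statistics)

All statistics (outlier mean/SD, quantile grids) are fitted on training
rows only, never on held-out test rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import warnings

import numpy as np
import scipy.signal

from spiketongue.dataio import NON_BEVERAGE, RawRecording

N_BEVERAGES = 5


@dataclass
class FilterSpec:
    """First-order high-pass: zero at 0 Hz, pole at ``pole_hz``, unity
    high-frequency gain; H(s) = s / (s + 2*pi*pole_hz)."""

    pole_hz: float = 5e-4
    sample_rate_hz: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pole_hz < self.sample_rate_hz / 2):
            raise ValueError("require 0 < pole_hz < Nyquist")

    def coefficients(self) -> tuple[np.ndarray, np.ndarray]:
        """Discrete (b, a) via the bilinear transform at ``sample_rate_hz``."""
        b, a = scipy.signal.bilinear(
            [1.0, 0.0], [1.0, 2.0 * np.pi * self.pole_hz], fs=self.sample_rate_hz
        )
        return b, a


@dataclass
class ChannelStats:
    """Fitted per-channel statistics: outlier gate and quantile map."""

    mean: float
    sd: float
    quantiles: np.ndarray       # sorted reference quantiles (training units)
    grid: np.ndarray            # uniform [0, 1] grid, same length
    session_id: int
    n_train: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0 (constant channel?)")
        if np.any(np.diff(self.quantiles) < 0):
            raise ValueError("quantile map must be non-decreasing")


@dataclass
class PreprocessModel:
    """Fitted preprocessing state: one :class:`ChannelStats` per
    (session, channel), plus the filter specification."""

    filter_spec: FilterSpec
    stats: dict[tuple[int, str], ChannelStats] = field(default_factory=dict)
    n_quantiles: int = 1000

    def save(self, path) -> None:
        payload = {
            "pole_hz": self.filter_spec.pole_hz,
            "sample_rate_hz": self.filter_spec.sample_rate_hz,
            "n_quantiles": self.n_quantiles,
            "stats": [
                {
                    "session": s, "channel": c, "mean": st.mean, "sd": st.sd,
                    "n_train": st.n_train,
                    "quantiles": st.quantiles.tolist(), "grid": st.grid.tolist(),
                }
                for (s, c), st in self.stats.items()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PreprocessModel":
        with open(path) as fh:
            payload = json.load(fh)
        model = cls(
            FilterSpec(payload["pole_hz"], payload["sample_rate_hz"]),
            n_quantiles=payload["n_quantiles"],
        )
        for item in payload["stats"]:
            model.stats[(item["session"], item["channel"])] = ChannelStats(
                mean=item["mean"], sd=item["sd"],
                quantiles=np.asarray(item["quantiles"]),
                grid=np.asarray(item["grid"]),
                session_id=item["session"], n_train=item["n_train"],
            )
        return model


# ---------------------------------------------------------------------------
# Stage 1: cycle balancing
# ---------------------------------------------------------------------------

def balance_cycles(rec: RawRecording, segment_length: int = 300) -> RawRecording:
    """Keep only complete, truncated measurement cycles.

    A (session, cycle) group is removed entirely unless all five beverages
    appear in it.  Within surviving cycles, any contiguous single-beverage
    segment longer than ``segment_length`` seconds is truncated to its
    first ``segment_length`` rows.  Non-beverage rows (label -1) are
    dropped.
    """
    keep = np.zeros(rec.n_measurements, dtype=bool)
    beverage = rec.labels != NON_BEVERAGE
    key = rec.session * (rec.cycle.max() + 2 if rec.n_measurements else 1) + rec.cycle
    for k in np.unique(key):
        in_cycle = key == k
        labs = set(rec.labels[in_cycle & beverage].tolist())
        if not labs >= set(range(N_BEVERAGES)):
            continue                      # incomplete cycle: drop entirely
        idx = np.flatnonzero(in_cycle & beverage)
        # split into contiguous same-label segments (by index adjacency+label)
        breaks = np.flatnonzero(
            (np.diff(idx) != 1) | (np.diff(rec.labels[idx]) != 0)
        ) + 1
        for seg in np.split(idx, breaks):
            keep[seg[:segment_length]] = True
    if not keep.any():
        warnings.warn("no complete measurement cycle found; recording is empty")
    return _subset(rec, keep)


def _subset(rec: RawRecording, mask: np.ndarray) -> RawRecording:
    return RawRecording(
        timestamps=rec.timestamps[mask],
        values=rec.values[mask] if rec.n_measurements else rec.values,
        labels=rec.labels[mask],
        session=rec.session[mask],
        cycle=rec.cycle[mask],
        channels=rec.channels,
    )


# ---------------------------------------------------------------------------
# Stage 2: high-pass filter
# ---------------------------------------------------------------------------

def highpass_filter(series: np.ndarray, spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the first-order high-pass to one channel series.

    The filter state is initialized at steady state for the first sample,
    so a constant series maps to exactly zero and no startup transient is
    introduced.  The series is treated as contiguous on the sample grid;
    removed rows leave implicit discontinuities.
    """
    spec = spec or FilterSpec()
    series = np.asarray(series, dtype=np.float64)
    if series.size == 0:
        return series.copy()
    b, a = spec.coefficients()
    zi = scipy.signal.lfilter_zi(b, a) * series[0]
    out, _ = scipy.signal.lfilter(b, a, series, zi=zi)
    return out


# ---------------------------------------------------------------------------
# Stage 3: outlier gate
# ---------------------------------------------------------------------------

def fit_outlier_stats(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and population SD over training rows."""
    values = np.atleast_2d(values)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    mean = values.mean(axis=0)
    sd = values.std(axis=0)     # population SD (ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant channel: sd = 0")
    return mean, sd


def remove_outliers(
    values: np.ndarray, mean: np.ndarray, sd: np.ndarray, n_sd: float = 4.0
) -> np.ndarray:
    """Row mask keeping measurements within ``n_sd`` SDs on every channel.

    A row is removed iff at least one channel is strictly further than
    ``n_sd * sd`` from the training mean; the boundary value is retained.
    """
    dev = np.abs(values - mean)
    return ~(dev > n_sd * sd).any(axis=1)


# ---------------------------------------------------------------------------
# Stage 4: quantile normalization
# ---------------------------------------------------------------------------

def fit_quantile_map(train: np.ndarray, n_quantiles: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Fit a monotone map equal to the training ECDF on a quantile grid.

    Conceptually the data is mapped to a normal distribution (rank-based
    Gaussianization) and then through the standard normal CDF onto
    [0, 1]; the composition of those two steps is the empirical CDF, which
    is what is stored: reference quantiles at ``n_quantiles`` evenly
    spaced probability levels.
    """
    train = np.asarray(train, dtype=np.float64).ravel()
    if train.size == 0:
        raise ValueError("empty training series")
    grid = np.linspace(0.0, 1.0, min(n_quantiles, train.size))
    quantiles = np.quantile(train, grid)
    return quantiles, grid


def apply_quantile_map(series: np.ndarray, quantiles: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Map values onto [0, 1] through the fitted quantile grid.

    Linear interpolation between reference quantiles; values outside the
    training range clip to 0 or 1.  Rank order is preserved.
    """
    return np.interp(np.asarray(series, dtype=np.float64), quantiles, grid)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def holdout_mask(rec: RawRecording) -> np.ndarray:
    """Training mask reserving the last complete cycle of the final session.

    Operates on a cycle-balanced recording (all remaining cycles complete);
    rows of the highest cycle id within the highest session id are test.
    """
    if rec.n_measurements == 0:
        raise ValueError("empty recording")
    last_session = rec.session.max()
    in_last = rec.session == last_session
    last_cycle = rec.cycle[in_last].max()
    return ~(in_last & (rec.cycle == last_cycle))


def preprocess(
    rec: RawRecording,
    train_mask: np.ndarray | None = None,
    filter_spec: FilterSpec | None = None,
    n_quantiles: int = 1000,
    segment_length: int = 300,
) -> tuple[RawRecording, PreprocessModel]:
    """Run the full per-session preprocessing pipeline.

    Parameters
    ----------
    rec : raw labeled recording
    train_mask : boolean mask over ``rec`` rows marking training data; by
        default everything except the last complete cycle of the final
        session (the chronological hold-out).  Statistics are fitted on
        training rows only.
    filter_spec, n_quantiles, segment_length : stage parameters.

    Returns
    -------
    (processed, model) : the processed recording (values in [0, 1],
        non-beverage rows and outliers removed, sessions concatenated) and
        the fitted :class:`PreprocessModel`.
    """
    spec = filter_spec or FilterSpec()
    balanced = balance_cycles(rec, segment_length=segment_length)
    if train_mask is None:
        mask_b = holdout_mask(balanced)
    else:
        train_mask = np.asarray(train_mask, dtype=bool)
        if train_mask.shape != (rec.n_measurements,):
            raise ValueError("train_mask must align with the input recording rows")
        # carry the mask through the row selection done by balance_cycles
        pos = {(s, t): i for i, (s, t) in enumerate(zip(rec.session, rec.timestamps))}
        mask_b = np.array(
            [train_mask[pos[(s, t)]] for s, t in zip(balanced.session, balanced.timestamps)]
        )

    model = PreprocessModel(filter_spec=spec, n_quantiles=n_quantiles)
    pieces: list[tuple[RawRecording, np.ndarray]] = []
    for sid in np.unique(balanced.session):
        in_sess = balanced.session == sid
        if not (mask_b & in_sess).any():
            raise ValueError(f"train_mask covers no rows of session {sid}")
        sess = _subset(balanced, in_sess)
        sess_train = mask_b[in_sess]

        filtered = np.column_stack(
            [highpass_filter(sess.values[:, j], spec) for j in range(sess.n_channels)]
        )
        mean, sd = fit_outlier_stats(filtered[sess_train])
        keep = remove_outliers(filtered, mean, sd)
        filtered, sess, sess_train = filtered[keep], _subset(sess, keep), sess_train[keep]

        out = np.empty_like(filtered)
        for j, ch in enumerate(sess.channels):
            quantiles, grid = fit_quantile_map(filtered[sess_train, j], n_quantiles)
            model.stats[(int(sid), ch)] = ChannelStats(
                mean=float(mean[j]), sd=float(sd[j]),
                quantiles=quantiles, grid=grid,
                session_id=int(sid), n_train=int(sess_train.sum()),
            )
            out[:, j] = apply_quantile_map(filtered[:, j], quantiles, grid)
        sess = RawRecording(
            timestamps=sess.timestamps, values=out, labels=sess.labels,
            session=sess.session, cycle=sess.cycle, channels=sess.channels,
        )
        pieces.append((sess, sess_train))

    processed = RawRecording(
        timestamps=np.concatenate([p.timestamps for p, _ in pieces]),
        values=np.concatenate([p.values for p, _ in pieces]),
        labels=np.concatenate([p.labels for p, _ in pieces]),
        session=np.concatenate([p.session for p, _ in pieces]),
        cycle=np.concatenate([p.cycle for p, _ in pieces]),
        channels=balanced.channels,
    )
    return processed, model
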