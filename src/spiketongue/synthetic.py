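"""Seeded generator of realistic electronic-tongue recordings.

The generator emulates the statistical structure of multiday beverage
tasting sessions recorded with an electrochemical microsensor array at
1 Hz:

* large per-beverage constant offsets that dominate over transient
  dynamics (ion activity, conductivity and redox levels differ far more
  between beverages than within one);
* first-order sensor settling when the array is moved between samples;
* slow drift (linear trend plus a Gaussian random walk), prominent on the
  charge-sensing ISFET channels;
* wash/transfer periods in deionized water, emitted with the non-beverage
  sentinel label -1 and higher variance;
* session-to-session offset and sensitivity changes, including discrete
  sensor replacements that redraw a channel's offset and gain.

Chemistry is encoded phenomenologically through the offsets matrix, not
through first-principles electrochemistry: the two wines are similar on
most channels, carbonation raises conductivity for sparkling water and
cava, and cava shares features of both groups.  Temperature and the
nitrate ISFET are constructed to be nearly uninformative (near-constant
offsets relative to their noise), mirroring the behaviour of stable
temperature readouts and erratic nitrate membranes in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import yaml

from spiketongue.dataio import CHANNELS, NON_BEVERAGE, RawRecording

N_BEVERAGES = 5

# Per-beverage baseline offsets, channel units, rows = white wine, red wine,
# still water, sparkling water, cava; columns = canonical channel order.
# TEMP (deg C) and ISF5 (mV) are near-constant across beverages by design.
_DEFAULT_OFFSETS = np.array(
    #  TEMP   ISF1   ISF2   ISF3   ISF4   ISF5   ISF6   COND   ORP
    [[22.00, 180.0, 260.0, 210.0, 140.0, 95.0, 120.0, 1.60, 420.0],   # white wine
     [22.02, 175.0, 270.0, 215.0, 150.0, 96.0, 118.0, 1.80, 380.0],   # red wine
     [21.98, 120.0, 150.0, 190.0, 100.0, 94.0, 160.0, 0.50, 520.0],   # still water
     [22.00, 130.0, 155.0, 230.0, 105.0, 95.0, 150.0, 1.30, 540.0],   # sparkling water
     [22.01, 170.0, 240.0, 220.0, 135.0, 95.5, 125.0, 1.90, 400.0]],  # cava
)

# Deionized wash water: low ionic content, low conductivity.
_WASH_OFFSETS = np.array([22.0, 100.0, 120.0, 170.0, 80.0, 93.0, 170.0, 0.05, 480.0])

_DEFAULT_NOISE_SD = np.array([0.05, 1.0, 1.2, 1.0, 1.0, 4.0, 1.0, 0.02, 3.0])
_DEFAULT_DRIFT_RATE = np.array([0.05, 2.0, 2.5, 2.0, 2.0, 3.0, 2.0, 0.01, 1.0])  # units/hour
_DEFAULT_SESSION_SHIFT_SD = np.array([0.3, 8.0, 8.0, 8.0, 8.0, 8.0, 8.0, 0.05, 10.0])

# Channels replaced before later sessions (redrawn offset and gain):
# session 2 replaces the Na+, Cl- and Ca2+ ISFETs; session 3 the pH and Cl-.
_DEFAULT_REPLACED: dict[int, tuple[str, ...]] = {
    2: ("ISF3", "ISF4", "ISF6"),
    3: ("ISF1", "ISF4"),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic recording generator.

    Defaults reproduce the recording protocol the generator emulates:
    three sessions, 5-minute beverage segments separated by 30 s washes,
    a transition circuit covering every ordered beverage pair, and sensor
    replacements before sessions 2 and 3.
    """

    n_sessions: int = 3
    segment_length: int = 300          # seconds per beverage segment
    wash_length: int = 30              # seconds of wash/transfer between segments
    offsets: np.ndarray = field(default_factory=lambda: _DEFAULT_OFFSETS.copy())
    wash_offsets: np.ndarray = field(default_factory=lambda: _WASH_OFFSETS.copy())
    transition_tau: float = 20.0       # sensor settling time constant, seconds
    drift_rate: np.ndarray = field(default_factory=lambda: _DEFAULT_DRIFT_RATE.copy())
    drift_walk_sd: float = 0.02        # random-walk drift, fraction of noise_sd per step
    noise_sd: np.ndarray = field(default_factory=lambda: _DEFAULT_NOISE_SD.copy())
    wash_noise_factor: float = 3.0     # non-beverage variance inflation
    session_shift_sd: np.ndarray = field(
        default_factory=lambda: _DEFAULT_SESSION_SHIFT_SD.copy())
    replaced_channels: dict[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_REPLACED))
    seed: int = 0

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (len(CHANNELS),)).copy()
        self.drift_rate = np.broadcast_to(
            np.asarray(self.drift_rate, dtype=float), (len(CHANNELS),)).copy()
        self.session_shift_sd = np.broadcast_to(
            np.asarray(self.session_shift_sd, dtype=float), (len(CHANNELS),)).copy()
        if self.offsets.shape != (N_BEVERAGES, len(CHANNELS)):
            raise ValueError(f"offsets must be {N_BEVERAGES}x{len(CHANNELS)}")
        if not (self.segment_length > self.transition_tau > 0):
            raise ValueError("require segment_length > transition_tau > 0")
        if (self.noise_sd < 0).any():
            raise ValueError("noise_sd must be >= 0")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "replaced_channels" in raw:
            raw["replaced_channels"] = {
                int(k): tuple(v) for k, v in raw["replaced_channels"].items()
            }
        return cls(**raw)


def transition_sequence(n_beverages: int, seed: int) -> list[int]:
    """Closed segment sequence covering every ordered beverage transition.

    Returns a list of beverage labels in which every ordered pair (a, b),
    a != b, occurs as a consecutive pair at least once; for ``n`` beverages
    this is an Eulerian circuit on the complete digraph K_n, hence exactly
    n(n-1) transitions (20 for five beverages) and n(n-1)+1 segments.
    Different seeds permute the circuit.
    """
    if n_beverages < 2:
        raise ValueError("need at least 2 beverages")
    g = nx.complete_graph(n_beverages, nx.DiGraph())
    # Seed-dependent relabeling varies the circuit while keeping coverage.
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_beverages)
    g = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(n_beverages)})
    edges = list(nx.eulerian_circuit(g, source=int(perm[0])))
    return [edges[0][0]] + [b for _, b in edges]


def _session_offsets(config: SyntheticConfig, session_id: int, rng: np.random.Generator):
    """Per-session beverage and wash offsets with shifts, replacements, gains."""
    shift = rng.normal(0.0, config.session_shift_sd)
    offsets = config.offsets + shift            # common-mode per-channel shift
    wash = config.wash_offsets + shift
    if session_id > 1:
        for ch in config.replaced_channels.get(session_id, ()):  # sensor swap
            j = CHANNELS.index(ch)
            big = rng.normal(0.0, 5.0 * config.session_shift_sd[j])
            gain = rng.uniform(0.7, 1.3)
            mean_j = config.offsets[:, j].mean()
            offsets[:, j] = mean_j + gain * (config.offsets[:, j] - mean_j) + big
            wash[j] = mean_j + gain * (config.wash_offsets[j] - mean_j) + big
    return offsets, wash


def generate_session(config: SyntheticConfig, session_id: int) -> RawRecording:
    """Generate one recording session as a :class:`RawRecording`.

    Within each segment the signal approaches the (session-perturbed)
    beverage offset exponentially with time constant ``transition_tau``
    from the previous segment's level, plus linear-plus-random-walk drift
    and i.i.d. Gaussian noise.  Wash/transfer periods between segments are
    emitted with label -1.  Deterministic given ``(config.seed, session_id)``.
    """
    if session_id < 1:
        raise ValueError("session_id must be >= 1")
    n_ch = len(CHANNELS)
    rng = np.random.default_rng([config.seed, session_id])
    seq = transition_sequence(N_BEVERAGES, seed=int(rng.integers(2**31)))
    offsets, wash_off = _session_offsets(config, session_id, rng)

    # Build the piecewise target schedule: segment, wash, segment, ...
    targets: list[np.ndarray] = []
    labels: list[int] = []
    lengths: list[int] = []
    for i, bev in enumerate(seq):
        if i > 0:
            targets.append(wash_off)
            labels.append(NON_BEVERAGE)
            lengths.append(config.wash_length)
        targets.append(offsets[bev])
        labels.append(bev)
        lengths.append(config.segment_length)

    n_total = int(sum(lengths))
    values = np.empty((n_total, n_ch))
    label_arr = np.empty(n_total, dtype=np.int64)
    cycle_arr = np.empty(n_total, dtype=np.int64)

    decay = np.exp(-1.0 / config.transition_tau)
    level = targets[0].astype(float).copy()     # start settled in first beverage
    row = 0
    cycle = 0
    seen: set[int] = set()
    for target, lab, length in zip(targets, labels, lengths):
        if lab != NON_BEVERAGE:
            if seen >= set(range(N_BEVERAGES)):
                cycle += 1                      # previous cycle covered all beverages
                seen = set()
            seen.add(lab)
        for _ in range(length):
            level = target + (level - target) * decay
            values[row] = level
            label_arr[row] = lab
            cycle_arr[row] = cycle
            row += 1

    # Drift: linear trend + Gaussian random walk, per channel.
    t_hours = np.arange(n_total) / 3600.0
    trend_sign = rng.choice([-1.0, 1.0], size=n_ch)
    values += t_hours[:, None] * (trend_sign * config.drift_rate)
    walk = np.cumsum(
        rng.normal(0.0, config.drift_walk_sd * config.noise_sd, size=(n_total, n_ch)),
        axis=0,
    )
    values += walk

    # Measurement noise, inflated during wash/transfer.
    sd = np.where(
        (label_arr == NON_BEVERAGE)[:, None],
        config.wash_noise_factor * config.noise_sd,
        config.noise_sd,
    )
    values += rng.normal(0.0, 1.0, size=values.shape) * sd

    return RawRecording(
        timestamps=np.arange(n_total, dtype=np.int64),
        values=values,
        labels=label_arr,
        session=np.full(n_total, session_id, dtype=np.int64),
        cycle=cycle_arr,
        channels=CHANNELS,
    )


def generate_dataset(config: SyntheticConfig) -> RawRecording:
    """Concatenate ``config.n_sessions`` generated sessions."""
    parts = [generate_session(config, sid) for sid in range(1, config.n_sessions + 1)]
    return RawRecording(
        timestamps=np.concatenate([p.timestamps for p in parts]),
        values=np.concatenate([p.values for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        session=np.concatenate([p.session for p in parts]),
        cycle=np.concatenate([p.cycle for p in parts]),
        channels=CHANNELS,
    )


def with_planted_noise_channel(config: SyntheticConfig, channel: str) -> SyntheticConfig:
    """Return a config where ``channel`` carries no beverage information.

    The channel's offsets are made identical across beverages (pure noise
    plus drift), which is the ground truth for sensor-importance recovery
    experiments.
    """
    j = CHANNELS.index(channel)
    offsets = config.offsets.copy()
    offsets[:, j] = offsets[:, j].mean()
    return replace(config, offsets=offsets)
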