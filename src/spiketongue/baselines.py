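"""Classification and sensor-selection baselines.

* k-nearest-neighbours on flattened preprocessed windows (the same
  inputs the CNN sees), with deterministic tie rules: distance ties break
  toward the lower training index, vote ties toward the lowest label.
* Random-forest Gini importance on single-measurement channel vectors,
  yielding one normalized importance value per sensor; used to select the
  most informative sensor subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.spatial.distance
from sklearn.ensemble import RandomForestClassifier

from spiketongue.dataio import CHANNELS
from spiketongue.windowing import WindowSet


@dataclass
class KnnConfig:
    k: int = 1
    sweep: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class ImportanceReport:
    """Normalized mean decrease in Gini impurity per channel."""

    channels: tuple[str, ...]
    importances: np.ndarray
    n_trees: int

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=float)
        if (self.importances < 0).any():
            raise ValueError("importances must be non-negative")

    def ranking(self) -> list[str]:
        """Channels from most to least important (ties by canonical order)."""
        order = np.argsort(-self.importances, kind="stable")
        return [self.channels[i] for i in order]


def _sorted_neighbor_labels(train_x, train_y, test_x):
    """Training labels sorted by distance per test point; distance ties
    break toward the lower training index (stable argsort)."""
    d = scipy.spatial.distance.cdist(test_x, train_x, metric="euclidean")
    order = np.argsort(d, axis=1, kind="stable")
    return train_y[order]


def knn_classify(train: WindowSet, test: WindowSet, cfg: KnnConfig) -> np.ndarray:
    """Majority vote among the k nearest flattened-window neighbours."""
    if len(train) == 0:
        raise ValueError("empty training set")
    if cfg.k > len(train):
        raise ValueError(f"k={cfg.k} exceeds {len(train)} training samples")
    nb = _sorted_neighbor_labels(train.flat(), train.labels, test.flat())[:, : cfg.k]
    n_classes = int(train.labels.max()) + 1
    votes = np.stack([(nb == c).sum(axis=1) for c in range(n_classes)], axis=1)
    return votes.argmax(axis=1)          # vote ties -> lowest label


def knn_sweep(train: WindowSet, test: WindowSet, ks) -> dict:
    """Accuracy for every k in one pass over sorted neighbour labels."""
    ks = [int(k) for k in ks]
    if any(k < 1 or k > len(train) for k in ks):
        raise ValueError("every k must satisfy 1 <= k <= n_train")
    nb = _sorted_neighbor_labels(train.flat(), train.labels, test.flat())
    n_classes = int(train.labels.max()) + 1
    accs = {}
    for k in ks:
        head = nb[:, :k]
        votes = np.stack([(head == c).sum(axis=1) for c in range(n_classes)], axis=1)
        pred = votes.argmax(axis=1)
        accs[k] = float((pred == test.labels).mean())
    best_k = max(accs, key=lambda k: (accs[k], -k))
    return {"accuracy": accs, "best_k": best_k, "best_accuracy": accs[best_k]}


def default_k_grid(n_train: int) -> list[int]:
    """Odd k values on a logarithmic grid from 1 up to n_train."""
    ks = np.unique(np.geomspace(1, max(n_train, 1), num=20).astype(int))
    ks = np.unique(np.where(ks % 2 == 0, ks + 1, ks))
    return [int(k) for k in ks if k <= n_train]


def rf_sensor_importance(
    measurements: np.ndarray, labels: np.ndarray,
    channels: tuple[str, ...] = CHANNELS,
    n_trees: int = 1000, seed: int = 0,
) -> ImportanceReport:
    """Random-forest Gini importance of each sensor channel.

    Fitted on per-measurement channel vectors (one feature per sensor), so
    the report carries exactly one importance value per channel; values
    are normalized to sum to 1.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes for importance ranking")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1,
    )
    rf.fit(np.asarray(measurements), labels)
    return ImportanceReport(
        channels=tuple(channels),
        importances=rf.feature_importances_,
        n_trees=n_trees,
    )


def select_top_sensors(report: ImportanceReport, n_keep: int) -> list[str]:
    """The ``n_keep`` most important channels, returned in canonical order."""
    if n_keep > len(report.channels):
        raise ValueError("n_keep exceeds number of channels")
    top = set(report.ranking()[:n_keep])
    return [c for c in CHANNELS if c in top] or [c for c in report.channels if c in top]
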