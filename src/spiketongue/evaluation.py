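"""Metrics and experiment drivers: per-class accuracy, confusion
matrices, online accuracy vs time delay, and the window-length sweep.

The headline accuracy figure throughout is the macro (per-class) accuracy:
the mean of class-conditional accuracies, robust to class imbalance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np
from sklearn.metrics import confusion_matrix

from spiketongue.dataio import RawRecording
from spiketongue.windowing import WindowSet, label_runs, make_windows, split_train_test

N_CLASSES = 5


@dataclass
class EvalReport:
    """Per-class and macro accuracy with the underlying confusion matrix."""

    confusion: np.ndarray           # [n_classes, n_classes] counts
    per_class_accuracy: np.ndarray
    macro_accuracy: float
    overall_accuracy: float

    def summary(self) -> str:
        lines = [f"macro accuracy: {100 * self.macro_accuracy:.1f}%"]
        for c, acc in enumerate(self.per_class_accuracy):
            lines.append(f"  class {c}: {100 * acc:.1f}%")
        return "\n".join(lines)


def evaluate(predictions, truth, n_classes: int = N_CLASSES) -> EvalReport:
    """Confusion matrix, per-class accuracies and their macro average."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    for arr in (predictions, truth):
        if ((arr < 0) | (arr >= n_classes)).any():
            raise ValueError(f"labels outside 0..{n_classes - 1}")
    cm = confusion_matrix(truth, predictions, labels=np.arange(n_classes))
    row = cm.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, np.diag(cm) / np.maximum(row, 1), np.nan)
    present = row > 0
    return EvalReport(
        confusion=cm,
        per_class_accuracy=per_class,
        macro_accuracy=float(np.nanmean(per_class[present])),
        overall_accuracy=float((predictions == truth).mean()) if len(truth) else float("nan"),
    )


def ensemble_report(reports: list[EvalReport]) -> dict:
    """Mean +/- SD of macro accuracy over independently seeded runs."""
    accs = [r.macro_accuracy for r in reports]
    return {"mean": float(np.mean(accs)), "sd": float(np.std(accs)), "runs": accs}


@dataclass
class DelayCurve:
    """Online accuracy as a function of delay since beverage onset.

    ``delays`` are elapsed steps since the first measurement of a segment;
    the first entry is ``T - 1``, the earliest step with a full window.
    ``binned`` holds means over consecutive 10-step bins.
    """

    delays: np.ndarray
    accuracy: np.ndarray
    n_predictions: np.ndarray
    binned_delays: np.ndarray
    binned_accuracy: np.ndarray
    bin_width: int = 10


def delay_accuracy(
    predict, rec: RawRecording, T: int, bin_width: int = 10,
) -> DelayCurve:
    """Per-delay online accuracy over the segments of a recording.

    ``predict`` maps an array of windows ``[n, T, N]`` to label
    predictions.  For every contiguous beverage segment, a prediction is
    made at every step from onset (the first possible one uses the window
    ending at step ``T - 1``); correctness is aggregated by elapsed delay
    and then binned into ``bin_width``-step means.
    """
    hits: dict[int, list[bool]] = {}
    for run in label_runs(rec.labels, rec.session):
        if len(run) < T:
            warnings.warn(f"segment of {len(run)} rows shorter than T={T}; skipped")
            continue
        idx = run[: len(run) - T + 1][:, None] + np.arange(T)
        pred = np.asarray(predict(rec.values[idx]))
        truth = rec.labels[run[0]]
        for j, p in enumerate(pred):
            hits.setdefault(T - 1 + j, []).append(bool(p == truth))
    delays = np.array(sorted(hits))
    acc = np.array([np.mean(hits[d]) for d in delays])
    n = np.array([len(hits[d]) for d in delays])
    bins = (delays - delays.min()) // bin_width
    b_delays = np.array([delays[bins == b].mean() for b in np.unique(bins)])
    b_acc = np.array([acc[bins == b].mean() for b in np.unique(bins)])
    return DelayCurve(delays, acc, n, b_delays, b_acc, bin_width)


def window_length_sweep(
    lengths, rec: RawRecording, train_config, seeds=(0, 1, 2, 3, 4),
    spec=None,
) -> dict:
    """Retrain and evaluate the CNN for each window length.

    ``rec`` must already be preprocessed.  For every length a fresh model
    per seed is trained on the chronological split, and mean +/- SD macro
    test accuracy is reported, together with the surviving sample count.
    """
    from spiketongue.cnn import CNNSpec, build_cnn, predict_ann, train_cnn

    spec = spec or CNNSpec()
    out: dict[int, dict] = {}
    for T in lengths:
        if T < spec.kernel_size:
            warnings.warn(f"window length {T} below kernel size; skipped")
            continue
        ws = make_windows(rec, T=T)
        train, test = split_train_test(ws, rec)
        reports = []
        for s in seeds:
            model = build_cnn(spec, T, rec.n_channels, seed=s)
            train_cnn(model, train, replace(train_config, seed=s))
            _, pred = predict_ann(model, test)
            reports.append(evaluate(pred, test.labels))
        out[int(T)] = {
            **ensemble_report(reports),
            "n_train": len(train),
            "n_test": len(test),
            "n_windows": len(ws),
        }
    return out
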