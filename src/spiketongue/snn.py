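"""Rate-based spiking conversion of the trained CNN and its clock-driven
integrate-and-fire simulation.

Conversion follows the data-based weight-normalization approach for
rate-coded spiking networks: the maximum ReLU activation of each layer is
identified with the 99th percentile of its pooled training-set activation
distribution (``lambda_l``), and weights are rescaled as

    W'_l = W_l * lambda_{l-1} / lambda_l

with the input scale fixed at 1 because quantile normalization already
bounds inputs to [0, 1].  Every hidden neuron is a non-leaky
integrate-and-fire unit with threshold 1 and reset by subtraction: at
each algorithmic step it integrates its synaptic drive into the membrane
potential V, and if V >= 1 it emits one spike and V decreases by 1.
Under this scheme a neuron's firing rate approximates its (normalized)
analog activation, with O(1 / n_steps) discretization error.

Input values are injected as constant bias currents into the first
spiking layer; the output softmax stage is kept as a non-spiking
accumulator whose membrane potentials after ``n_steps`` are decoded by
argmax (argmax of any monotone transform of the potentials — e.g. spike
rates or a softmax — is identical).

A hardware-independent energy proxy counts synaptic operations: each
spike costs its neuron's fan-out in additive operations, plus the
per-step input-bias integrations; this is compared against the
multiply-accumulate count of one dense CNN forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from spiketongue.cnn import CNNModel, _forward, _im2col, predict_ann
from spiketongue.windowing import WindowSet


@dataclass
class LayerScale:
    """Per-layer activation scales; ``scales[l]`` is the percentile of the
    pooled post-ReLU activation distribution of conv layer ``l``.  The
    input scale is fixed at 1."""

    scales: list[float]
    percentile: float = 99.0
    lambda_input: float = 1.0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales):
            raise ValueError("layer scales must be positive (dead layer?)")


@dataclass
class SNNModel:
    """Converted spiking network: rescaled weights, unit thresholds, and
    the simulation schedule."""

    weights: list[np.ndarray]      # same shapes as the source CNN
    scales: LayerScale
    T: int
    N: int
    kernel_size: int
    n_classes: int
    threshold: float = 1.0
    n_steps: int = 50
    quantize_bits: int | None = None   # optional fixed-point weight probe

    def __post_init__(self) -> None:
        if self.quantize_bits is not None:
            q = 2 ** (self.quantize_bits - 1) - 1
            self.weights = [
                np.round(w / np.abs(w).max() * q) / q * np.abs(w).max()
                for w in self.weights
            ]


@dataclass
class OpsReport:
    """Operation counts of one simulated window vs one dense forward pass."""

    snn_synaptic_ops: int
    snn_input_integrations: int
    ann_macs: int
    spike_counts: list[int] = field(default_factory=list)

    @property
    def snn_total_ops(self) -> int:
        return self.snn_synaptic_ops + self.snn_input_integrations


def compute_layer_scales(
    model: CNNModel, train: WindowSet, percentile: float = 99.0
) -> LayerScale:
    """Percentile of each conv layer's pooled training activations."""
    from spiketongue.cnn import layer_activations

    acts, _ = layer_activations(model, train)
    scales = []
    for a in acts:
        if not (a > 0).any():
            raise ValueError("dead layer: all activations are zero")
        scales.append(float(np.percentile(a.ravel(), percentile)))
    return LayerScale(scales=scales, percentile=percentile)


def convert_to_snn(
    model: CNNModel, scales: LayerScale, n_steps: int = 50,
    quantize_bits: int | None = None,
) -> SNNModel:
    """Rescale weights by successive layer scales; thresholds stay at 1.

    Connectivity and causal structure are identical to the CNN; the
    softmax head becomes a non-spiking accumulator scaled by the last
    conv layer's lambda.
    """
    if len(scales.scales) != len(model.weights) - 1:
        raise ValueError("one scale per conv layer required")
    lams = [scales.lambda_input] + list(scales.scales)
    weights = []
    for i, w in enumerate(model.weights[:-1]):
        weights.append(w.astype(np.float64) * (lams[i] / lams[i + 1]))
    # output accumulator: multiply by lambda of the last hidden layer so the
    # accumulated potential approximates n_steps * (logit / 1).
    weights.append(model.weights[-1].astype(np.float64) * lams[-1])
    return SNNModel(
        weights=weights, scales=scales, T=model.T, N=model.N,
        kernel_size=model.spec.kernel_size, n_classes=model.spec.n_classes,
        n_steps=n_steps, quantize_bits=quantize_bits,
    )


def _conv_fanout(T: int, k: int, c_out: int) -> np.ndarray:
    """Fan-out of each of the T time positions of a layer feeding a causal
    conv: position t drives outputs t .. t+k-1 (clipped), each with c_out
    kernels."""
    return c_out * np.minimum(k, T - np.arange(T))


def ann_mac_count(T: int, N: int, kernel_size: int = 4, kernels: int = 32,
                  n_conv_layers: int = 3, n_classes: int = 5) -> int:
    """Multiply-accumulates of one dense CNN forward pass (zero-padding
    positions counted, as in a dense implementation)."""
    macs = T * kernel_size * N * kernels
    macs += (n_conv_layers - 1) * T * kernel_size * kernels * kernels
    macs += T * kernels * n_classes
    return int(macs)


def simulate(
    snn: SNNModel, window: np.ndarray, n_steps: int | None = None,
    record: bool = True,
):
    """Simulate one T x N window for ``n_steps`` algorithmic steps.

    Returns ``(label, rasters, v_trace, ops)`` where ``rasters`` is a list
    of boolean spike arrays per spiking layer (input layer + conv layers)
    of shape ``[n_steps, T, C]``, ``v_trace`` the output-accumulator
    potentials per step ``[n_steps, n_classes]``, and ``ops`` an
    :class:`OpsReport`.
    """
    n_steps = snn.n_steps if n_steps is None else n_steps
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    window = np.asarray(window, dtype=np.float64)
    labels, counts, rasters, v_trace, ops = _simulate_batch(
        snn, window[None], n_steps, record=record
    )
    if not record:
        return labels[0], None, None, ops[0]
    return labels[0], [r[:, 0] for r in rasters], v_trace[:, 0], ops[0]


def _simulate_batch(snn: SNNModel, x: np.ndarray, n_steps: int, record: bool = False):
    """Vectorized clock-driven simulation of a batch of windows.

    Layer 0 is the input layer: each of its T x N neurons receives its
    (constant) normalized sensor value as a bias current every step.
    Hidden conv layers integrate weighted incoming spikes.  The output
    layer integrates without spiking.
    """
    if x.shape[1:] != (snn.T, snn.N):
        raise ValueError(f"window shape {x.shape[1:]} does not match ({snn.T}, {snn.N})")
    b = len(x)
    k = snn.kernel_size
    theta = snn.threshold
    conv_ws = snn.weights[:-1]
    w_out = snn.weights[-1]

    shapes = [(snn.T, snn.N)] + [(snn.T, w.shape[1]) for w in conv_ws]
    v = [np.zeros((b, *s)) for s in shapes]
    v_out = np.zeros((b, snn.n_classes))
    counts = [np.zeros((b, *s)) for s in shapes]
    rasters = [np.zeros((n_steps, b, *s), dtype=bool) for s in shapes] if record else None
    v_trace = np.zeros((n_steps, b, snn.n_classes)) if record else None

    for t in range(n_steps):
        spikes_prev = None
        for l, vl in enumerate(v):
            if l == 0:
                vl += x                           # bias-current input coding
            else:
                col = _im2col(spikes_prev, k)
                drive = col.reshape(-1, col.shape[-1]) @ conv_ws[l - 1]
                vl += drive.reshape(vl.shape)
            s = vl >= theta
            vl -= theta * s                       # reset by subtraction
            counts[l] += s
            if record:
                rasters[l][t] = s
            spikes_prev = s.astype(np.float64)
        v_out += spikes_prev.reshape(b, -1) @ w_out
        if record:
            v_trace[t] = v_out

    labels = v_out.argmax(axis=1)                 # ties break to lowest label

    # synaptic-operation proxy, per window
    fan = [_conv_fanout(snn.T, k, conv_ws[0].shape[1])[None, :, None]
           * np.ones((1, 1, snn.N))]
    for l in range(1, len(conv_ws)):
        fan.append(_conv_fanout(snn.T, k, conv_ws[l].shape[1])[None, :, None]
                   * np.ones((1, 1, conv_ws[l - 1].shape[1])))
    fan.append(np.full((1, snn.T, conv_ws[-1].shape[1]), snn.n_classes, dtype=float))
    ops = []
    for i in range(b):
        syn = sum(float((counts[l][i] * fan[l][0]).sum()) for l in range(len(counts)))
        ops.append(OpsReport(
            snn_synaptic_ops=int(round(syn)),
            snn_input_integrations=int(n_steps * snn.T * snn.N),
            ann_macs=ann_mac_count(
                snn.T, snn.N, k, conv_ws[0].shape[1],
                len(conv_ws), snn.n_classes),
            spike_counts=[int(c[i].sum()) for c in counts],
        ))
    return labels, counts, rasters, v_trace, ops


def count_ops(snn: SNNModel, window: np.ndarray, n_steps: int | None = None) -> OpsReport:
    """Operation-count report for one simulated window (energy proxy)."""
    _, _, _, ops = simulate(snn, window, n_steps=n_steps, record=False)
    return ops


def predict_snn(
    snn: SNNModel, windows: WindowSet | np.ndarray, n_steps: int | None = None,
    ann: CNNModel | None = None, batch_size: int = 256,
) -> dict:
    """Batch spiking inference with conversion diagnostics.

    Returns a dict with predicted ``labels``, mean per-window operation
    counts, and — when the source ``ann`` is given — the fraction of
    windows where SNN and ANN agree and the Pearson correlation between
    hidden-unit spike rates (rescaled by the layer scales) and the ANN's
    analog activations.
    """
    n_steps = snn.n_steps if n_steps is None else n_steps
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = windows.samples if isinstance(windows, WindowSet) else np.asarray(windows)
    labels = np.empty(len(x), dtype=np.int64)
    all_counts: list[list[np.ndarray]] = []
    syn_ops = []
    for lo in range(0, len(x), batch_size):
        lab, counts, _, _, ops = _simulate_batch(snn, x[lo:lo + batch_size], n_steps)
        labels[lo:lo + batch_size] = lab
        all_counts.append([c for c in counts])
        syn_ops.extend(o.snn_total_ops for o in ops)
    out = {
        "labels": labels,
        "n_steps": n_steps,
        "mean_snn_ops": float(np.mean(syn_ops)),
        "ann_macs": ann_mac_count(snn.T, snn.N, snn.kernel_size,
                                  snn.weights[0].shape[1], len(snn.weights) - 1,
                                  snn.n_classes),
    }
    if ann is not None:
        _, ann_labels = predict_ann(ann, x)
        out["agreement"] = float((labels == ann_labels).mean())
        from spiketongue.cnn import layer_activations

        acts, _ = layer_activations(ann, x)
        lams = snn.scales.scales
        rates, analog = [], []
        for l in range(1, len(all_counts[0]) if all_counts else 0):
            rate = np.concatenate([c[l] for c in all_counts]) / n_steps * lams[l - 1]
            rates.append(rate.ravel())
            analog.append(acts[l - 1].ravel())
        if rates:
            r = scipy.stats.pearsonr(np.concatenate(rates), np.concatenate(analog))
            out["rate_activation_correlation"] = float(r.statistic)
    return out
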