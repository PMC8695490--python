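"""Causal 1-D convolutional beverage classifier, implemented in numpy.

The network is deliberately small so it fits within tight neuromorphic
resource budgets after conversion: three causal 1-D convolutional layers
(kernel size 4, 32 kernels each, ReLU, left zero-padding so the time
length is preserved), followed by a flatten and a single fully-connected
softmax stage.  No biases and no normalization layers are used anywhere —
both degrade the fidelity of the subsequent rate-based spiking conversion.

Training uses categorical cross-entropy with a bounded-adaptive
optimizer (Adam-style moment estimates whose effective step size is
clipped between bounds that converge to a final SGD rate), global
gradient-norm clipping and L2 regularization.  The forward/backward pass
is written on im2col matrices so all heavy lifting is BLAS matmuls.
All randomness flows from a single integer seed; training is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spiketongue.windowing import WindowSet

N_CLASSES = 5


@dataclass
class CNNSpec:
    """Architecture of the causal convolutional classifier."""

    n_conv_layers: int = 3
    kernels_per_layer: int = 32
    kernel_size: int = 4
    n_classes: int = N_CLASSES


@dataclass
class TrainConfig:
    """Training recipe; every field is logged with the trained model."""

    lr: float = 1e-3               # initial adaptive rate
    final_lr: float = 0.1          # terminal SGD rate of the bound schedule
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    gamma: float = 1e-3            # bound convergence speed
    grad_clip: float = 1.0         # global gradient-norm clip
    weight_decay: float = 1e-4     # L2 coefficient
    batch_size: int = 128
    epochs: int = 1500
    seed: int = 0


@dataclass
class CNNModel:
    """Layer specification plus trained weights.

    ``weights`` holds, in order, one im2col kernel matrix of shape
    ``[kernel_size * c_in, kernels]`` per conv layer and the final dense
    matrix ``[T * kernels, n_classes]``.  There are no bias parameters.
    """

    spec: CNNSpec
    T: int
    N: int
    weights: list[np.ndarray]
    train_config: TrainConfig | None = None
    training_log: dict = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights))

    def save(self, path) -> None:
        """Portable container: layer name -> array (no framework needed)."""
        arrays = {f"layer_{i}": w for i, w in enumerate(self.weights)}
        np.savez(
            path, T=self.T, N=self.N,
            kernel_size=self.spec.kernel_size,
            kernels=self.spec.kernels_per_layer,
            n_conv_layers=self.spec.n_conv_layers,
            n_classes=self.spec.n_classes,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "CNNModel":
        z = np.load(path)
        spec = CNNSpec(
            n_conv_layers=int(z["n_conv_layers"]),
            kernels_per_layer=int(z["kernels"]),
            kernel_size=int(z["kernel_size"]),
            n_classes=int(z["n_classes"]),
        )
        weights = [z[f"layer_{i}"] for i in range(spec.n_conv_layers + 1)]
        return cls(spec=spec, T=int(z["T"]), N=int(z["N"]), weights=weights)


def build_cnn(spec: CNNSpec, T: int, N: int, seed: int = 0) -> CNNModel:
    """Initialize a model with He-normal weights (variance 2 / fan-in)."""
    if T < spec.kernel_size:
        raise ValueError(f"T={T} shorter than kernel size {spec.kernel_size}")
    rng = np.random.default_rng(seed)
    k, f = spec.kernel_size, spec.kernels_per_layer
    weights: list[np.ndarray] = []
    c_in = N
    for _ in range(spec.n_conv_layers):
        fan_in = k * c_in
        weights.append(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, f)).astype(np.float32)
        )
        c_in = f
    fan_in = T * f
    weights.append(
        rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, spec.n_classes)).astype(np.float32)
    )
    return CNNModel(spec=spec, T=T, N=N, weights=weights)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, T, C) -> (B, T, k*C) causal patches: row t holds inputs t-k+1..t."""
    b_, t_, c_ = x.shape
    xp = np.concatenate([np.zeros((b_, k - 1, c_), dtype=x.dtype), x], axis=1)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, T, C, k)
    return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b_, t_, k * c_)


def _forward(model: CNNModel, x: np.ndarray, keep: bool = False):
    """Forward pass; with ``keep`` retains intermediates for backprop."""
    k = model.spec.kernel_size
    a = x.astype(model.weights[0].dtype)
    cache = {"acts": [], "cols": []} if keep else None
    acts = []
    for w in model.weights[:-1]:
        col = _im2col(a, k)
        z = col.reshape(-1, col.shape[-1]) @ w
        a = np.maximum(z, 0.0).reshape(a.shape[0], a.shape[1], -1)
        acts.append(a)
        if keep:
            cache["cols"].append(col)
    flat = a.reshape(a.shape[0], -1)
    logits = flat @ model.weights[-1]
    if keep:
        cache["acts"] = acts
        cache["flat"] = flat
    return logits, acts, cache


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _backward(model: CNNModel, cache, dlogits: np.ndarray) -> list[np.ndarray]:
    """Gradients w.r.t. every weight matrix, same order as ``model.weights``."""
    k = model.spec.kernel_size
    grads = [np.zeros_like(w) for w in model.weights]
    grads[-1] = cache["flat"].T @ dlogits
    dflat = dlogits @ model.weights[-1].T
    b_, t_ = cache["acts"][-1].shape[:2]
    da = dflat.reshape(b_, t_, -1)
    for i in range(len(model.weights) - 2, -1, -1):
        a = cache["acts"][i]
        dz = da * (a > 0)                           # ReLU gate
        col = cache["cols"][i]
        kc = col.shape[-1]
        grads[i] = col.reshape(-1, kc).T @ dz.reshape(-1, dz.shape[-1])
        if i > 0:
            dcol = (dz.reshape(-1, dz.shape[-1]) @ model.weights[i].T).reshape(b_, t_, k, kc // k)
            c_in = kc // k
            dxp = np.zeros((b_, t_ + k - 1, c_in), dtype=dz.dtype)
            for kk in range(k):                     # scatter patches back
                dxp[:, kk:kk + t_] += dcol[:, :, kk]
            da = dxp[:, k - 1:]
    return grads


def predict_ann(model: CNNModel, windows) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities and argmax labels (ties -> lowest label index)."""
    x = windows.samples if isinstance(windows, WindowSet) else np.asarray(windows)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != (model.T, model.N):
        raise ValueError(f"window shape {x.shape[1:]} does not match model ({model.T}, {model.N})")
    probs = np.empty((len(x), model.spec.n_classes))
    for lo in range(0, len(x), 1024):
        logits, _, _ = _forward(model, x[lo:lo + 1024])
        probs[lo:lo + 1024] = _softmax(logits.astype(np.float64))
    return probs, probs.argmax(axis=1)


def layer_activations(model: CNNModel, windows):
    """Post-ReLU outputs of every conv layer plus the pre-softmax head input."""
    x = windows.samples if isinstance(windows, WindowSet) else np.asarray(windows)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != (model.T, model.N):
        raise ValueError("window shape does not match model")
    _, acts, _ = _forward(model, x)
    return acts, acts[-1].reshape(len(x), -1)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_cnn(model: CNNModel, train: WindowSet, cfg: TrainConfig) -> CNNModel:
    """Train in place on labeled windows; returns the same model.

    The per-epoch loss and accuracy log is stored in
    ``model.training_log``.  Deterministic given ``cfg.seed``.
    """
    labels = train.labels
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes to train")
    x_all = train.samples.astype(np.float32)
    y_all = np.eye(model.spec.n_classes, dtype=np.float32)[labels]
    n = len(x_all)
    rng = np.random.default_rng(cfg.seed)

    m = [np.zeros_like(w) for w in model.weights]
    v = [np.zeros_like(w) for w in model.weights]
    step = 0
    log_loss, log_acc = [], []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        ep_loss = 0.0
        ep_correct = 0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            logits, _, cache = _forward(model, xb, keep=True)
            p = _softmax(logits)
            ep_loss += float(-np.sum(np.log(np.clip(p[yb > 0], 1e-12, None))))
            ep_correct += int((p.argmax(1) == yb.argmax(1)).sum())
            grads = _backward(model, cache, (p - yb) / len(xb))
            for g, w in zip(grads, model.weights):
                g += cfg.weight_decay * w
            gnorm = float(np.sqrt(sum(float((g * g).sum()) for g in grads)))
            if gnorm > cfg.grad_clip:
                scale = cfg.grad_clip / gnorm
                for g in grads:
                    g *= scale
            step += 1
            lower = cfg.final_lr * (1.0 - 1.0 / (cfg.gamma * step + 1.0))
            upper = cfg.final_lr * (1.0 + 1.0 / (cfg.gamma * step))
            bc1 = 1.0 - cfg.beta1 ** step
            bc2 = 1.0 - cfg.beta2 ** step
            for w, g, mi, vi in zip(model.weights, grads, m, v):
                mi += (1.0 - cfg.beta1) * (g - mi)
                vi += (1.0 - cfg.beta2) * (g * g - vi)
                eta = np.clip(cfg.lr / (np.sqrt(vi / bc2) + cfg.eps), lower, upper)
                w -= (eta * (mi / bc1)).astype(w.dtype)
        log_loss.append(ep_loss / n)
        log_acc.append(ep_correct / n)
    model.train_config = cfg
    model.training_log = {"loss": log_loss, "accuracy": log_acc}
    return model


def train_ensemble(
    spec: CNNSpec, T: int, N: int, train: WindowSet, cfg: TrainConfig,
    seeds, eval_windows: WindowSet | None = None,
) -> tuple[list[CNNModel], dict]:
    """Train one model per seed; summarize mean +/- SD accuracy.

    Accuracy is evaluated on ``eval_windows`` when given, otherwise the
    final training accuracy of each run is summarized.
    """
    from dataclasses import replace

    models, accs = [], []
    for s in seeds:
        model = build_cnn(spec, T, N, seed=s)
        train_cnn(model, train, replace(cfg, seed=s))
        if eval_windows is not None:
            _, pred = predict_ann(model, eval_windows)
            acc = float((pred == eval_windows.labels).mean())
        else:
            acc = model.training_log["accuracy"][-1]
        models.append(model)
        accs.append(acc)
    summary = {
        "seeds": list(seeds),
        "accuracy": accs,
        "mean": float(np.mean(accs)),
        "sd": float(np.std(accs)),
    }
    return models, summary
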