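"""Gradient-based baseline trainers: mini-batch gradient descent and Adam.

The differentiable objective is the mean softmax cross-entropy of the
class scores against the true labels (the GA alone optimizes the raw
error rate, which has no useful gradient).  ``backward`` implements
reverse-mode differentiation through every layer type by hand — dense,
ReLU, flatten, 2x2 average pool, and valid convolution — and is checked
against central finite differences in the test suite.

Both trainers update the same flat weight vector the GA evolves:
``w <- w - alpha * g`` for gradient descent, and the bias-corrected
first/second-moment update for Adam.  One "iteration" is one mini-batch
update; batches cycle through the training set in seeded shuffled order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import network as net
from ._batching import BatchCycler

__all__ = [
    "GDConfig",
    "AdamConfig",
    "AdamState",
    "loss",
    "backward",
    "gd_step",
    "adam_step",
    "train_gd",
    "train_adam",
    "TrainResult",
]


@dataclass(frozen=True)
class GDConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    iterations: int = 100
    init_dist: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")


@dataclass(frozen=True)
class AdamConfig:
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    iterations: int = 100
    init_dist: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("beta1 and beta2 must be in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class AdamState:
    m: np.ndarray  # first-moment estimate
    v: np.ndarray  # second-moment estimate
    t: int = 0

    @classmethod
    def zeros(cls, n: int) -> "AdamState":
        return cls(m=np.zeros(n), v=np.zeros(n), t=0)


@dataclass
class TrainResult:
    weights: net.WeightSet
    loss_history: list[float]
    config: object
    initial_weights: net.WeightSet | None = None


# ---------------------------------------------------------------------------
# forward with cache, loss, backward


def _forward_cached(spec: net.NetworkSpec, ws: net.WeightSet, images: np.ndarray):
    """Forward pass keeping every intermediate needed for backprop."""
    cache: list[tuple] = []
    x = np.asarray(images, dtype=float)
    conv_i = 0
    for layer in spec.layers:
        if layer[0] == "conv":
            pre = net._conv_batch(x, ws.conv_filters[conv_i], ws.conv_biases[conv_i])
            cache.append(("conv", conv_i, x, pre))
            x = np.maximum(pre, 0.0)
            conv_i += 1
        else:
            cache.append(("pool", x.shape))
            x = net._pool_batch(x, spec.pool_window, spec.pool_stride)
    map_shape = x.shape
    flat = x.reshape(x.shape[0], -1)
    if spec.hidden_width > 0:
        pre_h = flat @ ws.dense_weights[0].T + ws.dense_biases[0]
        hidden = np.maximum(pre_h, 0.0)
    else:
        pre_h, hidden = None, flat
    w_out = ws.dense_weights[-1]
    logits = hidden @ w_out.T + ws.dense_biases[-1]
    return cache, map_shape, flat, pre_h, hidden, logits


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss(spec: net.NetworkSpec, weights: net.WeightSet, images, labels) -> float:
    """Mean categorical cross-entropy of the softmax scores on a batch."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("loss needs a non-empty batch")
    *_, logits = _forward_cached(spec, weights, np.asarray(images, dtype=float))
    probs = _softmax(logits)
    eps = 1e-300  # guard log(0) from perfectly confident wrong scores
    return float(-np.mean(np.log(probs[np.arange(labels.size), labels] + eps)))


def backward(spec: net.NetworkSpec, weights: net.WeightSet, images, labels) -> net.WeightSet:
    """Exact gradient of :func:`loss` w.r.t. every parameter, as a WeightSet.

    The batch gradient is the mean of per-example gradients.
    """
    if spec.output_mode != "softmax":
        raise ValueError("gradient training requires output_mode='softmax'")
    images = np.asarray(images, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("backward needs a non-empty batch")
    n = labels.size
    cache, map_shape, flat, pre_h, hidden, logits = _forward_cached(spec, weights, images)

    probs = _softmax(logits)
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    dlogits /= n

    grad = net.restore_weights(np.zeros(net.count_weights(spec)), spec)

    # output dense layer
    grad.dense_weights[-1] = dlogits.T @ hidden
    if spec.use_biases:
        grad.dense_biases[-1] = dlogits.sum(axis=0)
    dhidden = dlogits @ weights.dense_weights[-1]

    if spec.hidden_width > 0:
        dpre_h = dhidden * (pre_h > 0)
        grad.dense_weights[0] = dpre_h.T @ flat
        if spec.use_biases:
            grad.dense_biases[0] = dpre_h.sum(axis=0)
        dflat = dpre_h @ weights.dense_weights[0]
    else:
        dflat = dhidden

    dx = dflat.reshape(map_shape)
    k = spec.kernel_size
    for entry in reversed(cache):
        if entry[0] == "pool":
            _, in_shape = entry
            s = spec.pool_stride
            up = np.repeat(np.repeat(dx, s, axis=1), s, axis=2) / (s * s)
            full = np.zeros(in_shape)
            full[:, : up.shape[1], : up.shape[2]] = up  # truncated edge gets no gradient
            dx = full
        else:
            _, conv_i, x_in, pre = entry
            dpre = dx * (pre > 0)
            win = np.lib.stride_tricks.sliding_window_view(x_in, (k, k), axis=(1, 2))
            # win: (N, Ho, Wo, C, k, k); dpre: (N, Ho, Wo, F)
            dfilt = np.tensordot(dpre, win, axes=[(0, 1, 2), (0, 1, 2)])  # (F, C, k, k)
            grad.conv_filters[conv_i] = dfilt.transpose(0, 2, 3, 1)
            if spec.use_biases:
                grad.conv_biases[conv_i] = dpre.sum(axis=(0, 1, 2))
            # full correlation of dpre with spatially flipped filters -> dX
            pad = k - 1
            padded = np.pad(dpre, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
            gwin = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(1, 2))
            flipped = weights.conv_filters[conv_i][:, ::-1, ::-1, :]
            # gwin: (N, H, W, F, k, k); flipped: (F, k, k, C)
            dx = np.tensordot(gwin, flipped, axes=[(3, 4, 5), (0, 1, 2)])
    return grad


# ---------------------------------------------------------------------------
# update rules (on flat vectors)


def gd_step(w: np.ndarray, g: np.ndarray, alpha: float) -> np.ndarray:
    """Plain gradient-descent update ``w - alpha * g``."""
    w = np.asarray(w, dtype=float)
    g = np.asarray(g, dtype=float)
    if w.shape != g.shape:
        raise ValueError(f"shape mismatch: w {w.shape} vs g {g.shape}")
    return w - alpha * g


def adam_step(
    state: AdamState, w: np.ndarray, g: np.ndarray, config: AdamConfig
) -> tuple[AdamState, np.ndarray]:
    """One bias-corrected Adam update; returns the new state and weights."""
    w = np.asarray(w, dtype=float)
    g = np.asarray(g, dtype=float)
    if w.shape != g.shape or state.m.shape != w.shape:
        raise ValueError("w, g, and Adam state must share one shape")
    t = state.t + 1
    m = config.beta1 * state.m + (1 - config.beta1) * g
    v = config.beta2 * state.v + (1 - config.beta2) * g**2
    m_hat = m / (1 - config.beta1**t)
    v_hat = v / (1 - config.beta2**t)
    w_new = w - config.learning_rate * m_hat / (np.sqrt(v_hat) + config.epsilon)
    return AdamState(m=m, v=v, t=t), w_new


# ---------------------------------------------------------------------------
# training loops


def _train_loop(spec, train_set, config, update) -> TrainResult:
    images = train_set.pixels_array()
    labels = train_set.labels_array()
    if labels.size == 0:
        raise ValueError("empty training set")
    master = np.random.SeedSequence(config.seed)
    init_seq, batch_seq = master.spawn(2)
    ws = net.init_weights(spec, config.init_dist, np.random.default_rng(init_seq))
    w0 = ws.copy()
    w = net.flatten_weights(ws)
    cycler = BatchCycler(labels.size, config.batch_size, np.random.default_rng(batch_seq))
    history: list[float] = []
    for _ in range(config.iterations):
        idx = cycler.next_batch()
        bx, by = images[idx], labels[idx]
        ws = net.restore_weights(w, spec)
        history.append(loss(spec, ws, bx, by))
        g = net.flatten_weights(backward(spec, ws, bx, by))
        w = update(w, g)
    return TrainResult(
        weights=net.restore_weights(w, spec),
        loss_history=history,
        config=config,
        initial_weights=w0,
    )


def train_gd(spec: net.NetworkSpec, train_set, config: GDConfig) -> TrainResult:
    """Mini-batch gradient descent from a seeded random initialization."""
    return _train_loop(spec, train_set, config, lambda w, g: gd_step(w, g, config.learning_rate))


def train_adam(spec: net.NetworkSpec, train_set, config: AdamConfig) -> TrainResult:
    """Adam from a seeded random initialization."""
    state = AdamState.zeros(net.count_weights(spec))

    def update(w, g):
        nonlocal state
        state, w_new = adam_step(state, w, g, config)
        return w_new

    return _train_loop(spec, train_set, config, update)
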