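"""CNN architecture, forward pass, and the weight-matrix <-> vector codec.

The network is a plain feed-forward CNN for binary image classification:
a chain of 3x3 "valid" convolutions (each followed by ReLU), a 2x2
stride-2 average pool after every ``pool_every``-th convolution, a
flattening step, one optional fully connected hidden layer with ReLU,
and a 2-unit output layer whose logits are normalized to class scores.

All parameters live in a :class:`WeightSet` whose tensors can be
serialized losslessly into a single flat vector (:func:`flatten_weights`
/ :func:`restore_weights`).  That flat vector is the chromosome evolved
by the genetic-algorithm trainer; the gradient trainers update the same
vector with backpropagated gradients, so all three optimizers act on an
identical parameterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "NetworkSpec",
    "WeightSet",
    "ArchitectureError",
    "build_network",
    "count_weights",
    "init_weights",
    "convolve_valid",
    "average_pool",
    "relu",
    "sigmoid",
    "dense_forward",
    "forward",
    "predict",
    "flatten_weights",
    "restore_weights",
    "save_checkpoint",
    "load_checkpoint",
]


class ArchitectureError(ValueError):
    """Raised when a layer chain cannot be realized (a spatial dim would hit 0)."""


@dataclass(frozen=True)
class NetworkSpec:
    """Immutable architecture description with all derived shapes resolved.

    ``layers`` is the resolved chain: tuples ``("conv", f, out_shape)`` and
    ``("pool", out_shape)`` where ``out_shape`` is (H, W, channels) after
    the layer.  ``flatten_size`` is the length of the feature vector fed
    to the fully connected block.
    """

    input_shape: tuple[int, int, int] = (210, 210, 3)
    conv_filter_counts: tuple[int, ...] = (8, 8, 16, 16, 24, 24, 32, 32)
    kernel_size: int = 3
    pool_every: int = 2
    pool_window: int = 2
    pool_stride: int = 2
    hidden_width: int = 100
    num_classes: int = 2
    use_biases: bool = True
    output_mode: str = "softmax"  # or "sigmoid"
    layers: tuple = field(default=(), compare=False)
    flatten_size: int = field(default=0, compare=False)

    @property
    def n_weights(self) -> int:
        return count_weights(self)


def build_network(
    input_shape: Sequence[int] = (210, 210, 3),
    conv_filter_counts: Sequence[int] = (8, 8, 16, 16, 24, 24, 32, 32),
    kernel_size: int = 3,
    pool_every: int = 2,
    pool_window: int = 2,
    pool_stride: int = 2,
    hidden_width: int = 100,
    num_classes: int = 2,
    use_biases: bool = True,
    output_mode: str = "softmax",
) -> NetworkSpec:
    """Resolve the full layer chain and validate every intermediate shape.

    A 2x2 stride-2 average pool is inserted after every ``pool_every``-th
    convolution.  Construction fails with :class:`ArchitectureError` as
    soon as any convolution or pool would need more rows/columns than the
    incoming feature map provides.
    """
    h, w, c = (int(v) for v in input_shape)
    if h <= 0 or w <= 0 or c <= 0:
        raise ArchitectureError(f"input dimensions must be positive, got {input_shape}")
    if kernel_size < 1:
        raise ArchitectureError("kernel_size must be >= 1")
    if pool_window != pool_stride:
        raise ArchitectureError("only pool_window == pool_stride is supported")
    if output_mode not in ("softmax", "sigmoid"):
        raise ValueError(f"unknown output_mode {output_mode!r}")

    layers: list[tuple] = []
    k = kernel_size
    for i, f in enumerate(conv_filter_counts):
        if f <= 0:
            raise ArchitectureError(f"filter count must be positive, got {f}")
        if h < k or w < k:
            raise ArchitectureError(
                f"conv layer {i + 1}: {k}x{k} kernel does not fit a {h}x{w} map"
            )
        h, w, c = h - k + 1, w - k + 1, f
        layers.append(("conv", f, (h, w, c)))
        if pool_every > 0 and (i + 1) % pool_every == 0:
            if h < pool_window or w < pool_window:
                raise ArchitectureError(
                    f"pool after conv layer {i + 1}: {pool_window}x{pool_window} "
                    f"window does not fit a {h}x{w} map"
                )
            h, w = h // pool_stride, w // pool_stride
            layers.append(("pool", (h, w, c)))

    flatten_size = h * w * c
    return NetworkSpec(
        input_shape=tuple(int(v) for v in input_shape),
        conv_filter_counts=tuple(int(f) for f in conv_filter_counts),
        kernel_size=kernel_size,
        pool_every=pool_every,
        pool_window=pool_window,
        pool_stride=pool_stride,
        hidden_width=hidden_width,
        num_classes=num_classes,
        use_biases=use_biases,
        output_mode=output_mode,
        layers=tuple(layers),
        flatten_size=flatten_size,
    )


@dataclass
class WeightSet:
    """All trainable parameters of a network, in structured (per-layer) form.

    conv_filters[i] has shape (F, k, k, C_in); dense weights are (out, in)
    so a dense layer computes ``y = w @ x + b``.
    """

    spec: NetworkSpec
    conv_filters: list[np.ndarray]
    conv_biases: list[np.ndarray]
    dense_weights: list[np.ndarray]
    dense_biases: list[np.ndarray]

    def copy(self) -> "WeightSet":
        return WeightSet(
            self.spec,
            [a.copy() for a in self.conv_filters],
            [a.copy() for a in self.conv_biases],
            [a.copy() for a in self.dense_weights],
            [a.copy() for a in self.dense_biases],
        )

    def tensors(self) -> list[np.ndarray]:
        """All tensors in the frozen chromosome serialization order."""
        out: list[np.ndarray] = []
        for filt, bias in zip(self.conv_filters, self.conv_biases):
            out.append(filt)
            if self.spec.use_biases:
                out.append(bias)
        for w, b in zip(self.dense_weights, self.dense_biases):
            out.append(w)
            if self.spec.use_biases:
                out.append(b)
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightSet):
            return NotImplemented
        mine, theirs = self.tensors(), other.tensors()
        return len(mine) == len(theirs) and all(
            a.shape == b.shape and np.array_equal(a, b) for a, b in zip(mine, theirs)
        )


def _tensor_shapes(spec: NetworkSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Shapes of every parameter tensor in chromosome order."""
    shapes: list[tuple[str, tuple[int, ...]]] = []
    c_in = spec.input_shape[2]
    k = spec.kernel_size
    for i, f in enumerate(spec.conv_filter_counts):
        shapes.append((f"conv{i}_w", (f, k, k, c_in)))
        if spec.use_biases:
            shapes.append((f"conv{i}_b", (f,)))
        c_in = f
    in_dim = spec.flatten_size
    dense_dims = []
    if spec.hidden_width > 0:
        dense_dims.append(spec.hidden_width)
    dense_dims.append(spec.num_classes)
    for j, out_dim in enumerate(dense_dims):
        shapes.append((f"dense{j}_w", (out_dim, in_dim)))
        if spec.use_biases:
            shapes.append((f"dense{j}_b", (out_dim,)))
        in_dim = out_dim
    return shapes


def count_weights(spec: NetworkSpec) -> int:
    """Total number of trainable parameters (filters + dense + biases)."""
    return sum(int(np.prod(shape)) for _, shape in _tensor_shapes(spec))


def init_weights(
    spec: NetworkSpec,
    dist: str = "uniform",
    seed: int | np.random.Generator | None = 0,
    uniform_halfwidth: float = 0.1,
    normal_sd: float = 0.1,
) -> WeightSet:
    """Draw every parameter i.i.d. from ``uniform(-hw, hw)`` or ``N(0, sd^2)``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if dist == "uniform":
        draw = lambda shape: rng.uniform(-uniform_halfwidth, uniform_halfwidth, shape)
    elif dist == "normal":
        draw = lambda shape: rng.normal(0.0, normal_sd, shape)
    else:
        raise ValueError(f"unknown init distribution {dist!r} (use 'uniform' or 'normal')")

    ws = _empty_weightset(spec)
    _assign_in_order(ws, [draw(shape) for _, shape in _tensor_shapes(spec)])
    return ws


def _empty_weightset(spec: NetworkSpec) -> WeightSet:
    return WeightSet(spec, [], [], [], [])


def _assign_in_order(ws: WeightSet, tensors: list[np.ndarray]) -> None:
    """Distribute tensors (in chromosome order) into the structured fields."""
    spec = ws.spec
    it = iter(tensors)
    ws.conv_filters, ws.conv_biases = [], []
    for f in spec.conv_filter_counts:
        ws.conv_filters.append(np.asarray(next(it), dtype=float))
        ws.conv_biases.append(
            np.asarray(next(it), dtype=float) if spec.use_biases else np.zeros(f)
        )
    n_dense = 2 if spec.hidden_width > 0 else 1
    ws.dense_weights, ws.dense_biases = [], []
    for _ in range(n_dense):
        w = np.asarray(next(it), dtype=float)
        ws.dense_weights.append(w)
        ws.dense_biases.append(
            np.asarray(next(it), dtype=float) if spec.use_biases else np.zeros(w.shape[0])
        )


# ---------------------------------------------------------------------------
# layer primitives


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, np.asarray(x, dtype=float))


def sigmoid(x):
    """Logistic function 1/(1+exp(-x)), overflow-safe for large |x|."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def dense_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Affine map ``y = w @ x + b`` (w is (out, in))."""
    x, w, b = np.atleast_1d(np.asarray(x, float)), np.atleast_2d(np.asarray(w, float)), np.atleast_1d(np.asarray(b, float))
    if w.shape[1] != x.shape[-1] or w.shape[0] != b.shape[0]:
        raise ValueError(f"shape mismatch: w {w.shape}, x {x.shape}, b {b.shape}")
    return x @ w.T + b


def _conv_batch(x: np.ndarray, filters: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Valid stride-1 cross-correlation for a batch (N,H,W,C) -> (N,Ho,Wo,F)."""
    k = filters.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    # win: (N, Ho, Wo, C, k, k); filters: (F, k, k, C)
    out = np.tensordot(win, filters, axes=[(3, 4, 5), (3, 1, 2)])
    return out + biases


def convolve_valid(image: np.ndarray, filters: np.ndarray, biases=None) -> np.ndarray:
    """Valid (no padding) stride-1 convolution of one (H,W,C) map.

    Each output cell is the dot product of a filter with the aligned input
    patch, plus that filter's bias.  Filters span all input channels.
    """
    image = np.asarray(image, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if image.ndim == 2:
        image = image[:, :, None]
    if filters.ndim == 3:
        filters = filters[None]
    n_f, k, k2, c_f = filters.shape
    h, w, c = image.shape
    if k != k2:
        raise ValueError("filters must be square")
    if c_f != c:
        raise ValueError(f"filter depth {c_f} != input channels {c}")
    if h < k or w < k:
        raise ValueError(f"{k}x{k} kernel does not fit a {h}x{w} input")
    if biases is None:
        biases = np.zeros(n_f)
    biases = np.asarray(biases, dtype=float)
    if biases.shape != (n_f,):
        raise ValueError(f"expected {n_f} biases, got shape {biases.shape}")
    return _conv_batch(image[None], filters, biases)[0]


def _pool_batch(x: np.ndarray, window: int = 2, stride: int = 2) -> np.ndarray:
    n, h, w, f = x.shape
    ho, wo = h // stride, w // stride
    x = x[:, : ho * stride, : wo * stride]
    return x.reshape(n, ho, stride, wo, stride, f).mean(axis=(2, 4))


def average_pool(image: np.ndarray, window: int = 2, stride: int = 2) -> np.ndarray:
    """2x2 stride-2 mean pooling; a trailing odd row/column is dropped."""
    if window != stride:
        raise ValueError("only window == stride is supported")
    image = np.asarray(image, dtype=float)
    squeeze = image.ndim == 2
    if squeeze:
        image = image[:, :, None]
    h, w = image.shape[:2]
    if h < window or w < window:
        raise ValueError(f"input {h}x{w} smaller than pooling window {window}")
    out = _pool_batch(image[None], window, stride)[0]
    return out[:, :, 0] if squeeze else out


def _normalize_scores(logits: np.ndarray, mode: str) -> np.ndarray:
    """Turn a (N, num_classes) logit array into scores summing to 1 per row."""
    if mode == "softmax":
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)
    # sigmoid mode: squash each logit independently, then renormalize
    s = sigmoid(logits)
    return s / s.sum(axis=1, keepdims=True)


def forward_batch(spec: NetworkSpec, weights: WeightSet, images: np.ndarray) -> np.ndarray:
    """Class scores for a batch of images (N, H, W, C) -> (N, num_classes)."""
    images = np.asarray(images, dtype=float)
    if images.shape[1:] != spec.input_shape:
        raise ValueError(
            f"images shape {images.shape[1:]} does not match spec input {spec.input_shape}"
        )
    x = images
    conv_i = 0
    for layer in spec.layers:
        if layer[0] == "conv":
            x = relu(_conv_batch(x, weights.conv_filters[conv_i], weights.conv_biases[conv_i]))
            conv_i += 1
        else:
            x = _pool_batch(x, spec.pool_window, spec.pool_stride)
    flat = x.reshape(x.shape[0], -1)
    if flat.shape[1] != spec.flatten_size:
        raise ValueError("flatten size mismatch (weights do not match spec)")
    if spec.hidden_width > 0:
        flat = relu(flat @ weights.dense_weights[0].T + weights.dense_biases[0])
        w_out, b_out = weights.dense_weights[1], weights.dense_biases[1]
    else:
        w_out, b_out = weights.dense_weights[0], weights.dense_biases[0]
    logits = flat @ w_out.T + b_out
    return _normalize_scores(logits, spec.output_mode)


def forward(spec: NetworkSpec, weights: WeightSet, image: np.ndarray) -> np.ndarray:
    """Class scores for a single input image; entries are in [0,1] and sum to 1."""
    return forward_batch(spec, weights, np.asarray(image, dtype=float)[None])[0]


def predict(spec: NetworkSpec, weights: WeightSet, images: np.ndarray) -> np.ndarray:
    """Hard labels (argmax of class scores); ties resolve to class 0 (benign)."""
    images = np.asarray(images, dtype=float)
    if images.ndim == 3:
        images = images[None]
    scores = forward_batch(spec, weights, images)
    return np.argmax(scores, axis=1)


# ---------------------------------------------------------------------------
# chromosome codec


def flatten_weights(weights: WeightSet) -> np.ndarray:
    """Serialize a WeightSet into the flat chromosome vector.

    Order is frozen: conv layers in order (filter tensor row-major, then
    bias), then dense layers (weight matrix row-major, then bias).
    """
    return np.concatenate([t.ravel() for t in weights.tensors()])


def restore_weights(vector: np.ndarray, spec: NetworkSpec) -> WeightSet:
    """Exact inverse of :func:`flatten_weights`."""
    vector = np.asarray(vector, dtype=float).ravel()
    shapes = _tensor_shapes(spec)
    total = sum(int(np.prod(s)) for _, s in shapes)
    if vector.size != total:
        raise ValueError(f"vector length {vector.size} != count_weights(spec) = {total}")
    tensors, pos = [], 0
    for _, shape in shapes:
        n = int(np.prod(shape))
        tensors.append(vector[pos : pos + n].reshape(shape))
        pos += n
    ws = _empty_weightset(spec)
    _assign_in_order(ws, tensors)
    return ws


# ---------------------------------------------------------------------------
# checkpoints


def _spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "input_shape": list(spec.input_shape),
        "conv_filter_counts": list(spec.conv_filter_counts),
        "kernel_size": spec.kernel_size,
        "pool_every": spec.pool_every,
        "pool_window": spec.pool_window,
        "pool_stride": spec.pool_stride,
        "hidden_width": spec.hidden_width,
        "num_classes": spec.num_classes,
        "use_biases": spec.use_biases,
        "output_mode": spec.output_mode,
    }


def spec_from_dict(d: dict) -> NetworkSpec:
    return build_network(**d)


def save_checkpoint(path, spec: NetworkSpec, weights: WeightSet) -> None:
    """Write spec + all parameter tensors to a single ``.npz`` archive."""
    arrays = {f"t{i:03d}": t for i, t in enumerate(weights.tensors())}
    arrays["spec_json"] = np.frombuffer(
        json.dumps(_spec_to_dict(spec)).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[NetworkSpec, WeightSet]:
    """Read a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as data:
        spec = spec_from_dict(json.loads(bytes(data["spec_json"]).decode()))
        names = sorted(k for k in data.files if k != "spec_json")
        tensors = [data[k] for k in names]
    ws = _empty_weightset(spec)
    _assign_in_order(ws, tensors)
    return spec, ws
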