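"""A small, fully deterministic feed-forward network engine.

The package trains two kinds of multilayer perceptrons — a sigmoid
autoencoder and a tanh regression network — at desk scale. Everything here
is plain numpy: explicit forward passes that expose pre-activations (the
attribution engine consumes them), manual backpropagation, Adam updates,
inverted dropout, and MAE/MSE losses with an optional L2 weight penalty.

Conventions: a layer computes ``a = f(W @ x + b)`` with ``W`` of shape
(out, in); data matrices carry one sample per column, matching the
genes × samples orientation of :class:`~landmarker.matrix.ExpressionMatrix`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "LayerSpec",
    "Layer",
    "NetworkParams",
    "ACTIVATIONS",
    "activation_fn",
    "activation_derivative",
    "init_network",
    "forward",
    "forward_full",
    "l2_penalty",
    "loss_value",
    "train_network",
    "save_network",
    "load_network",
]


# ---------------------------------------------------------------------------
# activations

ACTIVATIONS = ("sigmoid", "tanh", "linear")


def activation_fn(tag: str):
    if tag == "sigmoid":
        return expit
    if tag == "tanh":
        return np.tanh
    if tag == "linear":
        return lambda z: z
    raise ValueError(f"unknown activation {tag!r}")


def activation_derivative(tag: str):
    """Derivative as a function of the *pre-activation* z."""
    if tag == "sigmoid":
        def dsig(z):
            s = expit(z)
            return s * (1.0 - s)
        return dsig
    if tag == "tanh":
        return lambda z: 1.0 - np.tanh(z) ** 2
    if tag == "linear":
        return lambda z: np.ones_like(np.asarray(z, dtype=float))
    raise ValueError(f"unknown activation {tag!r}")


# ---------------------------------------------------------------------------
# parameters


@dataclass
class LayerSpec:
    """Architecture of one layer: width, activation tag, dropout rate."""

    width: int
    activation: str = "sigmoid"
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("layer width must be >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class Layer:
    """Weights (out × in), bias (out,) and activation tag of one layer."""

    W: np.ndarray
    b: np.ndarray
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if self.W.ndim != 2 or self.b.shape != (self.W.shape[0],):
            raise ValueError("W must be (out, in) and b must be (out,)")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class NetworkParams:
    """Ordered layers plus the index of the bottleneck (narrowest) layer."""

    layers: list = field(default_factory=list)
    bottleneck_index: int = 0

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("network needs at least one layer")
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.W.shape[1] != prev.W.shape[0]:
                raise ValueError(
                    f"layer dimension mismatch: {prev.W.shape} -> {nxt.W.shape}"
                )
        if not 0 <= self.bottleneck_index < len(self.layers):
            raise ValueError("bottleneck_index out of range")

    @property
    def input_dim(self) -> int:
        return self.layers[0].W.shape[1]

    @property
    def widths(self) -> list:
        return [layer.W.shape[0] for layer in self.layers]


def init_network(
    input_dim: int,
    specs: list,
    seed: int = 0,
    bottleneck_index: int | None = None,
) -> NetworkParams:
    """Glorot-uniform initialization, seeded; biases start at zero.

    ``bottleneck_index`` defaults to the narrowest non-final layer (the
    autoencoder convention); pass it explicitly for other topologies.
    """
    rng = np.random.default_rng(seed)
    layers = []
    fan_in = input_dim
    for spec in specs:
        limit = np.sqrt(6.0 / (fan_in + spec.width))
        W = rng.uniform(-limit, limit, size=(spec.width, fan_in))
        layers.append(Layer(W=W, b=np.zeros(spec.width), activation=spec.activation))
        fan_in = spec.width
    if bottleneck_index is None:
        widths = [s.width for s in specs]
        candidates = widths[:-1] if len(widths) > 1 else widths
        bottleneck_index = int(np.argmin(candidates))
    return NetworkParams(layers=layers, bottleneck_index=bottleneck_index)


# ---------------------------------------------------------------------------
# forward passes


def _check_input(params: NetworkParams, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != params.input_dim:
        raise ValueError(
            f"input has {x.shape[0]} features, network expects {params.input_dim}"
        )
    return x


def forward(params: NetworkParams, x: np.ndarray) -> list:
    """Inference-mode forward pass; returns every layer's activation.

    ``x`` may be a vector (one sample) or a matrix with samples as columns.
    Dropout is never applied here.
    """
    return forward_full(params, x)[0]


def forward_full(params: NetworkParams, x: np.ndarray):
    """Forward pass returning (activations, pre-activations) per layer."""
    a = _check_input(params, x)
    vector_input = a.ndim == 1
    if vector_input:
        a = a[:, None]
    activations, preacts = [], []
    for layer in params.layers:
        z = layer.W @ a + layer.b[:, None]
        a = activation_fn(layer.activation)(z)
        preacts.append(z[:, 0] if vector_input else z)
        activations.append(a[:, 0] if vector_input else a)
        if vector_input:
            a = activations[-1][:, None]
    return activations, preacts


# ---------------------------------------------------------------------------
# losses


def l2_penalty(params: NetworkParams, l2_alpha: float) -> float:
    """alpha × sum of squared weight entries over all layers (biases excluded)."""
    if l2_alpha == 0:
        return 0.0
    return float(l2_alpha * sum(np.sum(layer.W**2) for layer in params.layers))


def loss_value(
    g: np.ndarray,
    g_hat: np.ndarray,
    params: NetworkParams | None = None,
    l2_alpha: float = 0.0,
    loss: str = "mae",
) -> float:
    """Data loss (MAE or MSE over all entries) plus the L2 weight penalty."""
    g = np.asarray(g, dtype=float)
    g_hat = np.asarray(g_hat, dtype=float)
    if g.shape != g_hat.shape:
        raise ValueError(f"shape mismatch {g.shape} vs {g_hat.shape}")
    if loss == "mae":
        data = float(np.mean(np.abs(g - g_hat)))
    elif loss == "mse":
        data = float(np.mean((g - g_hat) ** 2))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    penalty = l2_penalty(params, l2_alpha) if params is not None else 0.0
    return data + penalty


# ---------------------------------------------------------------------------
# training


def train_network(
    params: NetworkParams,
    X_in: np.ndarray,
    X_out: np.ndarray,
    *,
    loss: str = "mae",
    epochs: int = 100,
    batch_size: int = 256,
    l2_alpha: float = 0.0,
    dropout_rates: list | None = None,
    seed: int = 0,
    learning_rate: float = 1e-3,
    beta1: float = 0.9,
    beta2: float = 0.999,
    eps: float = 1e-8,
) -> list:
    """Train in place with Adam; returns the per-epoch mean batch loss.

    ``dropout_rates`` gives one inverted-dropout rate per layer (applied to
    that layer's output during training only); the output layer's rate must
    be zero. Identical seed, data and initial parameters reproduce the run
    bit for bit. A non-finite loss aborts with a diagnostic rather than
    silently training on NaNs.
    """
    if loss not in ("mae", "mse"):
        raise ValueError(f"unknown loss {loss!r}")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    X_in = np.asarray(X_in, dtype=np.float64)
    X_out = np.asarray(X_out, dtype=np.float64)
    if X_in.ndim != 2 or X_out.ndim != 2 or X_in.shape[1] != X_out.shape[1]:
        raise ValueError("X_in and X_out must be 2-D with matching sample counts")
    n_layers = len(params.layers)
    if dropout_rates is None:
        dropout_rates = [0.0] * n_layers
    if len(dropout_rates) != n_layers:
        raise ValueError("one dropout rate per layer required")
    if dropout_rates[-1] != 0:
        raise ValueError("no dropout on the output layer")

    rng = np.random.default_rng(seed)
    m_state = [np.zeros_like(layer.W) for layer in params.layers]
    v_state = [np.zeros_like(layer.W) for layer in params.layers]
    mb_state = [np.zeros_like(layer.b) for layer in params.layers]
    vb_state = [np.zeros_like(layer.b) for layer in params.layers]
    t = 0

    n_samples = X_in.shape[1]
    history: list = []
    for epoch in range(epochs):
        order = rng.permutation(n_samples)
        batch_losses = []
        for start in range(0, n_samples, batch_size):
            idx = order[start : start + batch_size]
            A_prev = X_in[:, idx]
            G = X_out[:, idx]
            mb = idx.size

            # forward with dropout
            acts = [A_prev]
            preacts = []
            masks = []
            for li, layer in enumerate(params.layers):
                z = layer.W @ acts[-1] + layer.b[:, None]
                a = activation_fn(layer.activation)(z)
                p = dropout_rates[li]
                if p > 0:
                    mask = (rng.random(a.shape) >= p) / (1.0 - p)
                    a = a * mask
                else:
                    mask = None
                preacts.append(z)
                masks.append(mask)
                acts.append(a)

            out = acts[-1]
            batch_loss = loss_value(G, out, params, l2_alpha, loss=loss)
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss ({batch_loss}) at epoch {epoch + 1}; "
                    "lower the learning rate or check the input scaling"
                )
            batch_losses.append(batch_loss)

            # backward
            n_out = out.shape[0]
            diff = out - G
            if loss == "mae":
                dA = np.sign(diff) / (n_out * mb)
            else:
                dA = 2.0 * diff / (n_out * mb)
            t += 1
            grads_W = [None] * n_layers
            grads_b = [None] * n_layers
            for li in range(n_layers - 1, -1, -1):
                layer = params.layers[li]
                if masks[li] is not None:
                    dA = dA * masks[li]
                dZ = dA * activation_derivative(layer.activation)(preacts[li])
                grads_W[li] = dZ @ acts[li].T + 2.0 * l2_alpha * layer.W
                grads_b[li] = dZ.sum(axis=1)
                if li > 0:
                    dA = layer.W.T @ dZ

            # Adam update
            for li, layer in enumerate(params.layers):
                for grad, state_m, state_v, target in (
                    (grads_W[li], m_state, v_state, "W"),
                    (grads_b[li], mb_state, vb_state, "b"),
                ):
                    state_m[li] = beta1 * state_m[li] + (1 - beta1) * grad
                    state_v[li] = beta2 * state_v[li] + (1 - beta2) * grad**2
                    m_hat = state_m[li] / (1 - beta1**t)
                    v_hat = state_v[li] / (1 - beta2**t)
                    step = learning_rate * m_hat / (np.sqrt(v_hat) + eps)
                    if target == "W":
                        layer.W = layer.W - step
                    else:
                        layer.b = layer.b - step

        history.append(float(np.mean(batch_losses)))
    return history


# ---------------------------------------------------------------------------
# persistence


def save_network(path: str, params: NetworkParams, meta: dict | None = None) -> None:
    """Persist a network (and optional metadata) to a ``.npz`` archive.

    float64 arrays round-trip bit-exactly through ``numpy.savez``.
    """
    payload = {
        "n_layers": np.array(len(params.layers)),
        "bottleneck_index": np.array(params.bottleneck_index),
        "activations": np.array([layer.activation for layer in params.layers]),
        "meta_json": np.array(json.dumps(meta or {})),
    }
    for i, layer in enumerate(params.layers):
        payload[f"W{i}"] = layer.W
        payload[f"b{i}"] = layer.b
    np.savez(path, **payload)


def load_network(path: str):
    """Inverse of :func:`save_network`; returns (params, meta)."""
    with np.load(path, allow_pickle=False) as data:
        n_layers = int(data["n_layers"])
        activations = [str(a) for a in data["activations"]]
        layers = [
            Layer(W=data[f"W{i}"], b=data[f"b{i}"], activation=activations[i])
            for i in range(n_layers)
        ]
        params = NetworkParams(
            layers=layers, bottleneck_index=int(data["bottleneck_index"])
        )
        meta = json.loads(str(data["meta_json"]))
    return params, meta
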