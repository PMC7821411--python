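"""The sigmoid autoencoder that learns nonlinear inter-gene structure.

A symmetric 500–100–500 architecture (widths configurable) with sigmoid
activations throughout, trained with mean-absolute-error loss plus a small
L2 weight penalty (alpha = 1e-6) using Adam for a fixed 100 epochs with 10%
dropout on the wide hidden layers. The 100-unit bottleneck is the compressed
representation; its activations feed both the sample-clustering check and
the DeepLIFT attribution stage.

Expression data must be scaled to [0, 1] first (``preprocess.minmax_to_unit``)
because every layer, including the output, is sigmoid. Reconstruction errors
on the unit scale convert to the [4, 15] expression scale by the factor
``high - low``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .matrix import ExpressionMatrix

__all__ = [
    "DEFAULT_HIDDEN_WIDTHS",
    "TrainConfig",
    "AutoencoderModel",
    "build_architecture",
    "train",
    "forward",
    "reconstruct",
    "encode",
    "loss",
]

DEFAULT_HIDDEN_WIDTHS = (500, 100, 500)


@dataclass
class TrainConfig:
    """Autoencoder training hyperparameters.

    Defaults: 100 epochs, L2 alpha 1e-6, 10% dropout, Adam with the
    conventional step size 1e-3 and moment decays (0.9, 0.999).
    """

    epochs: int = 100
    l2_alpha: float = 1e-6
    dropout_rate: float = 0.10
    batch_size: int = 256
    seed: int = 0
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.l2_alpha < 0:
            raise ValueError("l2_alpha must be >= 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class AutoencoderModel:
    """Trained parameters plus the expression-scale bounds they assume."""

    params: nn.NetworkParams
    low: float = 4.0
    high: float = 15.0
    config: TrainConfig | None = None

    def save(self, path: str) -> None:
        meta = {"low": self.low, "high": self.high}
        if self.config is not None:
            meta["config"] = asdict(self.config)
        nn.save_network(path, self.params, meta)

    @classmethod
    def load(cls, path: str) -> "AutoencoderModel":
        params, meta = nn.load_network(path)
        config = TrainConfig(**meta["config"]) if "config" in meta else None
        return cls(
            params=params,
            low=float(meta.get("low", 4.0)),
            high=float(meta.get("high", 15.0)),
            config=config,
        )


def build_architecture(
    n_genes: int,
    hidden_widths=DEFAULT_HIDDEN_WIDTHS,
    dropout_rate: float = 0.10,
):
    """Layer specs for a symmetric sigmoid autoencoder.

    Dropout is attached to every hidden layer except the bottleneck (the
    attribution stage reads the bottleneck, which must stay noise-free) and
    never to the output layer. Returns (specs, bottleneck_index).
    """
    hidden_widths = list(hidden_widths)
    if not hidden_widths:
        raise ValueError("need at least one hidden layer")
    bottleneck = int(np.argmin(hidden_widths))
    specs = [
        nn.LayerSpec(
            width=w,
            activation="sigmoid",
            dropout_rate=0.0 if i == bottleneck else dropout_rate,
        )
        for i, w in enumerate(hidden_widths)
    ]
    specs.append(nn.LayerSpec(width=n_genes, activation="sigmoid", dropout_rate=0.0))
    return specs, bottleneck


def train(
    X_unit: ExpressionMatrix,
    hidden_widths=DEFAULT_HIDDEN_WIDTHS,
    config: TrainConfig | None = None,
):
    """Train the autoencoder on a unit-scaled matrix; returns (params, history).

    The input doubles as the reconstruction target. Seed-reproducible: the
    same data, architecture and config give bit-identical parameters.
    """
    if config is None:
        config = TrainConfig()
    v = X_unit.values
    if v.min() < -1e-9 or v.max() > 1 + 1e-9:
        raise ValueError("train expects unit-scaled data; apply minmax_to_unit first")
    specs, bottleneck = build_architecture(
        X_unit.n_genes, hidden_widths, config.dropout_rate
    )
    params = nn.init_network(
        X_unit.n_genes, specs, seed=config.seed, bottleneck_index=bottleneck
    )
    history = nn.train_network(
        params,
        v,
        v,
        loss="mae",
        epochs=config.epochs,
        batch_size=config.batch_size,
        l2_alpha=config.l2_alpha,
        dropout_rates=[s.dropout_rate for s in specs],
        seed=config.seed,
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        eps=config.eps,
    )
    return params, history


def forward(params: nn.NetworkParams, x: np.ndarray) -> list:
    """Inference-mode forward pass returning every layer's activations."""
    return nn.forward(params, x)


def reconstruct(params: nn.NetworkParams, x: np.ndarray) -> np.ndarray:
    """Full encode-then-decode pass; the final layer's activations."""
    return nn.forward(params, x)[-1]


def encode(params: nn.NetworkParams, x: np.ndarray) -> np.ndarray:
    """Bottleneck activations — the compressed representation of ``x``."""
    return nn.forward(params, x)[params.bottleneck_index]


def loss(
    g: np.ndarray,
    g_hat: np.ndarray,
    params: nn.NetworkParams | None = None,
    l2_alpha: float = 0.0,
) -> float:
    """Mean absolute error plus ``l2_alpha`` × sum of squared weights."""
    return nn.loss_value(g, g_hat, params, l2_alpha, loss="mae")
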