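"""Landmark → target expression inference (the D-GEX role).

A feed-forward regression network maps the expression of the landmark genes
to the expression of every remaining (target) gene; how well it does is the
operational measure of how much genomic information a landmark set carries.
The desk-scale default is one hidden layer of 200 tanh units with a linear
output trained on mean squared error (Adam, 200 epochs, batch 256); a
``paper_scale_spec`` preset with 9000 hidden units mirrors the published
scale of this architecture family but is far beyond desk-scale testing.

Both sides are affinely scaled to [0, 1] for training (bounds remembered by
the model) and predictions are mapped back to the expression scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .attribution import LandmarkSet
from .matrix import ExpressionMatrix

__all__ = [
    "RegressorSpec",
    "InferenceModel",
    "paper_scale_spec",
    "split_landmark_target",
    "train_regressor",
    "predict_targets",
]


@dataclass
class RegressorSpec:
    """Architecture and training schedule of the landmark→target regressor."""

    hidden_widths: tuple = (200,)
    hidden_activation: str = "tanh"
    epochs: int = 200
    batch_size: int = 256
    seed: int = 0
    learning_rate: float = 1e-3
    l2_alpha: float = 0.0

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.hidden_activation not in ("tanh", "sigmoid"):
            raise ValueError("hidden activation must be tanh or sigmoid")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def paper_scale_spec(seed: int = 0) -> RegressorSpec:
    """One hidden layer of 9000 units — the published scale of this design."""
    return RegressorSpec(hidden_widths=(9000,), seed=seed)


@dataclass
class InferenceModel:
    """Trained regressor with the gene sets and scaling bounds it assumes."""

    params: nn.NetworkParams
    landmark_gene_ids: list
    target_gene_ids: list
    in_bounds: tuple = (4.0, 15.0)
    out_bounds: tuple = (4.0, 15.0)

    def __post_init__(self) -> None:
        if set(self.landmark_gene_ids) & set(self.target_gene_ids):
            raise ValueError("landmark and target gene sets must be disjoint")
        if self.params.input_dim != len(self.landmark_gene_ids):
            raise ValueError("network input width must equal landmark count")
        if self.params.widths[-1] != len(self.target_gene_ids):
            raise ValueError("network output width must equal target count")


# ---------------------------------------------------------------------------


def split_landmark_target(X: ExpressionMatrix, landmarks: LandmarkSet):
    """Partition the gene rows of ``X`` into (landmark, target) matrices.

    Landmark rows come out in landmark rank order; targets keep the original
    row order. Sample order is untouched. Missing landmark ids are reported
    explicitly.
    """
    index = X.gene_index()
    missing = [g for g in landmarks.gene_ids if g not in index]
    if missing:
        raise KeyError(f"landmark genes absent from matrix: {missing}")
    landmark_set = set(landmarks.gene_ids)
    target_ids = [g for g in X.gene_ids if g not in landmark_set]
    return X.subset_genes(landmarks.gene_ids), X.subset_genes(target_ids)


def _bounds_of(values: np.ndarray):
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        hi = lo + 1.0  # constant matrix: any affine map works
    return lo, hi


def _to_unit(values: np.ndarray, bounds) -> np.ndarray:
    lo, hi = bounds
    return (values - lo) / (hi - lo)


def _from_unit(values: np.ndarray, bounds) -> np.ndarray:
    lo, hi = bounds
    return lo + values * (hi - lo)


def train_regressor(
    landmark_X: ExpressionMatrix,
    target_X: ExpressionMatrix,
    spec: RegressorSpec | None = None,
):
    """Fit the regressor; returns (InferenceModel, loss history).

    With ``hidden_widths=()`` the model is multivariate linear regression
    fitted by the same optimizer. Seed-reproducible.
    """
    if spec is None:
        spec = RegressorSpec()
    if landmark_X.sample_ids != target_X.sample_ids:
        raise ValueError("landmark and target matrices must share sample columns")
    in_bounds = _bounds_of(landmark_X.values)
    out_bounds = _bounds_of(target_X.values)
    X_in = _to_unit(landmark_X.values, in_bounds)
    X_out = _to_unit(target_X.values, out_bounds)

    specs = [
        nn.LayerSpec(width=w, activation=spec.hidden_activation)
        for w in spec.hidden_widths
    ]
    specs.append(nn.LayerSpec(width=target_X.n_genes, activation="linear"))
    params = nn.init_network(
        landmark_X.n_genes, specs, seed=spec.seed, bottleneck_index=0
    )
    history = nn.train_network(
        params,
        X_in,
        X_out,
        loss="mse",
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        l2_alpha=spec.l2_alpha,
        seed=spec.seed,
        learning_rate=spec.learning_rate,
    )
    model = InferenceModel(
        params=params,
        landmark_gene_ids=list(landmark_X.gene_ids),
        target_gene_ids=list(target_X.gene_ids),
        in_bounds=in_bounds,
        out_bounds=out_bounds,
    )
    return model, history


def predict_targets(
    model: InferenceModel, landmark_X: ExpressionMatrix
) -> ExpressionMatrix:
    """Predict target-gene expression for each sample column.

    Landmark rows are matched by gene id (order in the input matrix does not
    matter); the output is on the original expression scale with one row per
    target gene.
    """
    index = landmark_X.gene_index()
    missing = [g for g in model.landmark_gene_ids if g not in index]
    if missing:
        raise KeyError(f"landmark genes absent from input: {missing}")
    ordered = landmark_X.subset_genes(model.landmark_gene_ids)
    X_in = _to_unit(ordered.values, model.in_bounds)
    out_unit = nn.forward(model.params, X_in)[-1]
    return ExpressionMatrix(
        _from_unit(out_unit, model.out_bounds),
        list(model.target_gene_ids),
        list(landmark_X.sample_ids),
    )
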