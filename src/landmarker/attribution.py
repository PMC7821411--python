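"""DeepLIFT Rescale-rule attribution of input genes to bottleneck units.

Gradient saliency assigns zero importance wherever a sigmoid saturates;
DeepLIFT instead scores each input by its *difference from a reference*:
every nonlinearity contributes the finite-difference slope

    m = (f(z) - f(z0)) / (z - z0)

between the reference pre-activation ``z0`` and the actual pre-activation
``z`` (falling back to the analytic derivative when the two nearly
coincide), and linear layers contribute their weight matrices. Chaining the
multipliers from each bottleneck unit back to the inputs and multiplying by
``x - reference`` yields contributions that satisfy *summation-to-delta*:
for every bottleneck unit t,

    sum_i C[i, t] = encode(x)_t - encode(reference)_t  (exactly).

Only the encoder sub-network (input → bottleneck) is read; the decoder
plays no role in gene importance. Per-gene importance is the mean of
|contributions| over samples and bottleneck units, and the landmark set is
the top k (default 943, the size of the L1000 landmark panel) of that
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .matrix import ExpressionMatrix

__all__ = [
    "ReferenceInput",
    "ContributionTensor",
    "ImportanceRanking",
    "LandmarkSet",
    "rescale_multiplier",
    "encoder_layers",
    "propagate_contributions",
    "compute_contribution_tensor",
    "reference_from_training",
    "aggregate_importance",
    "select_landmarks",
]

DEFAULT_K = 943
_UNIT_TOL = 1e-6
_GRADIENT_EPS = 1e-7


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ReferenceInput:
    """The baseline expression profile differences are measured against."""

    values: np.ndarray
    source: str = "custom"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.source not in ("train_mean", "zeros", "custom"):
            raise ValueError(f"unknown reference source {self.source!r}")
        if self.values.min() < -_UNIT_TOL or self.values.max() > 1 + _UNIT_TOL:
            raise ValueError("reference values must lie in [0, 1]")


@dataclass
class ContributionTensor:
    """Scores indexed (sample, input gene, bottleneck unit)."""

    scores: np.ndarray
    sample_ids: list = field(default_factory=list)
    gene_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 3:
            raise ValueError("scores must be (samples, genes, units)")
        if len(self.sample_ids) != self.scores.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if len(self.gene_ids) != self.scores.shape[1]:
            raise ValueError("gene_ids length mismatch")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("contribution scores must be finite")


@dataclass
class ImportanceRanking:
    """Genes ordered by non-increasing importance score."""

    gene_ids: list
    scores: np.ndarray
    tie_break: str = "gene_id"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.gene_ids) != self.scores.size:
            raise ValueError("gene_ids and scores length mismatch")
        if np.any(np.diff(self.scores) > 1e-15):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def rank_of(self) -> dict:
        """Map gene id -> 0-based rank position."""
        return {g: i for i, g in enumerate(self.gene_ids)}


@dataclass
class LandmarkSet:
    """The selected landmark genes, in rank order."""

    gene_ids: list
    k: int

    def __post_init__(self) -> None:
        if len(self.gene_ids) != self.k:
            raise ValueError("landmark list length must equal k")
        if len(set(self.gene_ids)) != self.k:
            raise ValueError("duplicate landmark ids")


# ---------------------------------------------------------------------------
# the Rescale rule


def rescale_multiplier(x, x0, activation: str, epsilon: float = _GRADIENT_EPS):
    """Finite-difference slope of an activation between x0 and x.

    Vectorized over arrays. Where |x - x0| < epsilon the slope is replaced
    by the analytic derivative at x0 (the standard numerical-stability
    fallback); for a linear tag the slope is identically 1.
    """
    f = nn.activation_fn(activation)
    fprime = nn.activation_derivative(activation)
    x = np.asarray(x, dtype=np.float64)
    x0 = np.asarray(x0, dtype=np.float64)
    dz = x - x0
    near = np.abs(dz) < epsilon
    safe_dz = np.where(near, 1.0, dz)
    slope = np.where(near, fprime(x0), (f(x) - f(x0)) / safe_dz)
    if slope.ndim == 0:
        return float(slope)
    return slope


def encoder_layers(params: nn.NetworkParams) -> list:
    """The input → bottleneck sub-network (inclusive)."""
    return params.layers[: params.bottleneck_index + 1]


def _encoder_multiplier_matrix(
    params: nn.NetworkParams, x: np.ndarray, ref: np.ndarray
) -> np.ndarray:
    """Multiplier of every bottleneck unit w.r.t. every input, (units × genes).

    Linear rule for the affine part (the weight matrix) and the Rescale rule
    for each nonlinearity, chained from the input forward.
    """
    layers = encoder_layers(params)
    M = None  # multiplier of the current layer's activations w.r.t. inputs
    a, a0 = x, ref
    for layer in layers:
        z = layer.W @ a + layer.b
        z0 = layer.W @ a0 + layer.b
        m_act = rescale_multiplier(z, z0, layer.activation)
        prop = layer.W if M is None else layer.W @ M
        M = np.asarray(m_act)[:, None] * prop
        a = nn.activation_fn(layer.activation)(z)
        a0 = nn.activation_fn(layer.activation)(z0)
    return M


def propagate_contributions(
    params: nn.NetworkParams, x: np.ndarray, ref: ReferenceInput
) -> np.ndarray:
    """Contribution of every input gene to every bottleneck unit for one sample.

    Returns a (n_genes × n_bottleneck) matrix whose column sums equal
    ``encode(x) - encode(ref)`` (summation-to-delta). Inputs and reference
    must be on the unit scale.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != params.input_dim:
        raise ValueError(
            f"input has {x.shape[0]} genes, network expects {params.input_dim}"
        )
    if ref.values.shape[0] != params.input_dim:
        raise ValueError("reference length does not match network input width")
    if x.min() < -_UNIT_TOL or x.max() > 1 + _UNIT_TOL:
        raise ValueError("input must be on the unit scale [0, 1]")
    M = _encoder_multiplier_matrix(params, x, ref.values)
    return M.T * (x - ref.values)[:, None]


def compute_contribution_tensor(
    params: nn.NetworkParams,
    X_unit: ExpressionMatrix,
    ref: ReferenceInput,
    n_samples: int | None = None,
    seed: int = 0,
) -> ContributionTensor:
    """Rescale contributions for every sample of a unit-scaled matrix.

    ``n_samples`` optionally restricts attribution to a seeded subsample
    (useful on large compendia); default is all samples.
    """
    idx = np.arange(X_unit.n_samples)
    if n_samples is not None and n_samples < X_unit.n_samples:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(X_unit.n_samples, size=n_samples, replace=False))
    scores = np.empty(
        (idx.size, X_unit.n_genes, encoder_layers(params)[-1].W.shape[0])
    )
    for out_i, col in enumerate(idx):
        scores[out_i] = propagate_contributions(params, X_unit.values[:, col], ref)
    return ContributionTensor(
        scores=scores,
        sample_ids=[X_unit.sample_ids[i] for i in idx],
        gene_ids=list(X_unit.gene_ids),
    )


# ---------------------------------------------------------------------------
# reference, ranking, selection


def reference_from_training(X_unit: ExpressionMatrix) -> ReferenceInput:
    """Per-gene mean of the (unit-scaled) training matrix.

    A mean reference makes importance measure deviation from typical
    expression rather than from an arbitrary all-zero profile.
    """
    if X_unit.n_genes == 0 or X_unit.n_samples == 0:
        raise ValueError("empty matrix has no reference")
    return ReferenceInput(
        values=X_unit.values.mean(axis=1), source="train_mean"
    )


def aggregate_importance(
    C: ContributionTensor, signed: bool = False
) -> ImportanceRanking:
    """Collapse a contribution tensor to one importance score per gene.

    Default: mean of |contribution| over samples and bottleneck units, so
    opposing effects across units cannot cancel. ``signed=True`` instead
    takes |mean signed contribution|.
    """
    if C.scores.size == 0:
        raise ValueError("empty contribution tensor")
    if signed:
        per_gene = np.abs(C.scores.mean(axis=(0, 2)))
    else:
        per_gene = np.abs(C.scores).mean(axis=(0, 2))
    gene_arr = np.array(C.gene_ids)
    # descending score, ties broken by ascending gene id
    order = np.lexsort((gene_arr, -per_gene))
    return ImportanceRanking(
        gene_ids=list(gene_arr[order]),
        scores=per_gene[order],
        tie_break="gene_id",
    )


def select_landmarks(ranking: ImportanceRanking, k: int = DEFAULT_K) -> LandmarkSet:
    """Top-k genes of the ranking, order preserved."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k must be in [1, {len(ranking)}], got {k}")
    return LandmarkSet(gene_ids=list(ranking.gene_ids[:k]), k=k)
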