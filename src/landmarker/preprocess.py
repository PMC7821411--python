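"""Normalization, deduplication and splitting of expression compendia.

The pipeline's data preparation mirrors the standard microarray-compendium
recipe: quantile normalization of every sample onto a common distribution
rescaled into [4, 15], k-means-assisted removal of near-duplicate profiles,
and a seeded ~90/10 train/test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import KMeans

from .matrix import ExpressionMatrix

__all__ = [
    "SplitResult",
    "quantile_normalize",
    "build_reference_distribution",
    "apply_reference_distribution",
    "deduplicate_profiles",
    "train_test_split",
    "minmax_to_unit",
    "unit_to_minmax",
]

_RANGE_TOL = 1e-9


@dataclass
class SplitResult:
    """A seeded, disjoint partition of samples into train and test."""

    train: ExpressionMatrix
    test: ExpressionMatrix
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train.sample_ids) & set(self.test.sample_ids)
        if overlap:
            raise ValueError(f"train/test share samples: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# quantile normalization


def _map_columns_to_reference(values: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Replace each column by the reference distribution at its ranks.

    Ties get the average rank; the reference is linearly interpolated at
    fractional ranks, the standard mean-order-statistic construction.
    """
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = rankdata(values[:, j], method="average")
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        frac = ranks - np.floor(ranks)
        # exact indexing at integer ranks; linear blend only at .5 tie ranks,
        # so tied values map identically in every column
        out[:, j] = reference[lo] * (1.0 - frac) + reference[hi] * frac
    return out


def quantile_normalize(
    X: ExpressionMatrix, low: float = 4.0, high: float = 15.0
) -> ExpressionMatrix:
    """Quantile-normalize all samples, then rescale globally into [low, high].

    Every column is forced onto the cross-sample mean of order statistics,
    so afterwards all columns share one value distribution; a single affine
    map then pins the global minimum to ``low`` and maximum to ``high``.

    Raises ``ValueError`` for single-sample input (nothing to equalize
    against) and for constant matrices (zero range cannot be rescaled).
    """
    if X.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if X.n_genes < 2:
        raise ValueError("quantile normalization needs at least 2 genes")
    if high <= low:
        raise ValueError("high must exceed low")
    reference = np.sort(X.values, axis=0).mean(axis=1)
    mapped = _map_columns_to_reference(X.values, reference)
    lo, hi = mapped.min(), mapped.max()
    if hi - lo < _RANGE_TOL:
        raise ValueError("constant matrix: zero range cannot be rescaled")
    # divide before scaling so the endpoints land on low/high exactly
    rescaled = low + ((mapped - lo) / (hi - lo)) * (high - low)
    return X.with_values(rescaled)


def build_reference_distribution(X: ExpressionMatrix) -> np.ndarray:
    """Mean order statistics of a (normalized) training matrix.

    Stored so that samples from a new platform can be mapped onto the same
    distribution (joint quantile normalization against a fixed reference).
    The result is non-decreasing with one entry per gene.
    """
    if X.n_genes == 0 or X.n_samples == 0:
        raise ValueError("empty matrix has no reference distribution")
    return np.sort(X.values, axis=0).mean(axis=1)


def apply_reference_distribution(
    X: ExpressionMatrix, reference: np.ndarray
) -> ExpressionMatrix:
    """Map every column of ``X`` onto a stored reference distribution."""
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (X.n_genes,):
        raise ValueError(
            f"reference length {reference.shape} does not match {X.n_genes} genes"
        )
    if np.any(np.diff(reference) < 0):
        raise ValueError("reference distribution must be non-decreasing")
    return X.with_values(_map_columns_to_reference(X.values, reference))


# ---------------------------------------------------------------------------
# duplicate-profile removal


def deduplicate_profiles(
    X: ExpressionMatrix,
    n_clusters: int | None = None,
    corr_threshold: float = 0.99,
    seed: int = 0,
) -> ExpressionMatrix:
    """Drop near-duplicate samples, using k-means only to limit comparisons.

    Samples are partitioned by k-means on their expression vectors; within
    each cluster they are scanned in input order and a sample is kept iff
    its Pearson correlation with every already-kept sample of the cluster
    is below ``corr_threshold``. With ``n_clusters=1`` this degenerates to
    the exact all-pairs scan, which defines correctness; clustering merely
    accelerates it on large compendia.
    """
    if corr_threshold <= 0:
        raise ValueError("corr_threshold must be positive")
    if n_clusters is None:
        n_clusters = min(100, X.n_samples)
    if not 1 <= n_clusters <= X.n_samples:
        raise ValueError("n_clusters must be in [1, n_samples]")

    if n_clusters == 1:
        labels = np.zeros(X.n_samples, dtype=int)
    else:
        km = KMeans(
            n_clusters=n_clusters,
            init="k-means++",
            n_init=10,
            max_iter=300,
            tol=1e-4,
            random_state=seed,
        )
        labels = km.fit_predict(X.values.T)

    keep_mask = np.zeros(X.n_samples, dtype=bool)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size == 1:
            keep_mask[members] = True
            continue
        # correlation among cluster members; constant profiles give NaN,
        # treated as uncorrelated
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X.values[:, members].T)
        corr = np.nan_to_num(corr, nan=0.0)
        kept_local: list[int] = []
        for pos in range(members.size):
            if all(corr[pos, q] < corr_threshold for q in kept_local):
                kept_local.append(pos)
        keep_mask[members[kept_local]] = True

    return X.subset_samples(np.flatnonzero(keep_mask))


# ---------------------------------------------------------------------------
# train/test split


def train_test_split(
    X: ExpressionMatrix, train_fraction: float = 0.9, seed: int = 0
) -> SplitResult:
    """Seeded uniform split of samples; floor(n × fraction) go to training.

    The same seed always yields the identical partition. Original sample
    order is preserved inside each half.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = X.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return SplitResult(
        train=X.subset_samples(train_idx),
        test=X.subset_samples(test_idx),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# [low, high] <-> [0, 1] scaling (the sigmoid output layer works on [0, 1])


def minmax_to_unit(
    X: ExpressionMatrix, low: float = 4.0, high: float = 15.0
) -> ExpressionMatrix:
    """Affine map of a [low, high] matrix onto [0, 1]."""
    v = X.values
    if v.min() < low - _RANGE_TOL or v.max() > high + _RANGE_TOL:
        raise ValueError(
            f"values outside [{low}, {high}] (observed "
            f"[{v.min():.6g}, {v.max():.6g}])"
        )
    return X.with_values((v - low) / (high - low))


def unit_to_minmax(
    X: ExpressionMatrix, low: float = 4.0, high: float = 15.0
) -> ExpressionMatrix:
    """Inverse of :func:`minmax_to_unit`."""
    v = X.values
    if v.min() < -_RANGE_TOL or v.max() > 1 + _RANGE_TOL:
        raise ValueError(
            f"values outside [0, 1] (observed [{v.min():.6g}, {v.max():.6g}])"
        )
    return X.with_values(low + v * (high - low))
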