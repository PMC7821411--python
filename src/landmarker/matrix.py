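"""Expression-matrix container used throughout the pipeline.

Genes are rows, samples are columns — the orientation of GCT files and of
most microarray compendia. Values are expected to be on a log-like scale
(e.g. quantile-normalized into [4, 15]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A genes × samples matrix with gene and sample identifiers.

    Invariants (enforced at construction):

    * ``values`` is a finite 2-D float array of shape (n_genes, n_samples);
    * ``gene_ids`` and ``sample_ids`` are unique and match the array shape.
    """

    values: np.ndarray
    gene_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n_genes, n_samples = self.values.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} rows"
            )
        if len(self.sample_ids) != n_samples:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samples} columns"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("duplicate sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), list(self.gene_ids), list(self.sample_ids)
        )

    # -- indexing ----------------------------------------------------------

    def gene_index(self) -> dict:
        """Map gene id -> row index."""
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_samples(self, indices) -> "ExpressionMatrix":
        """New matrix holding the given sample columns (by position)."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            list(self.gene_ids),
            [self.sample_ids[i] for i in idx],
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        """New matrix holding the given gene rows, in the order requested."""
        index = self.gene_index()
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"gene ids not in matrix: {missing[:10]}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            self.values[rows, :], [str(g) for g in gene_ids], list(self.sample_ids)
        )

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Same ids, new value array (shape must match)."""
        return ExpressionMatrix(values, list(self.gene_ids), list(self.sample_ids))

    # -- pandas bridge -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=np.float64), list(df.index), list(df.columns))
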