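"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported formats:

* TSV/CSV expression tables — genes as rows, first column gene id, header
  row of sample ids;
* GCT v1.2 — the ``#1.2`` dialect (header line, dimensions line, then
  ``Name``/``Description`` columns before the samples);
* gene lists — one identifier per line, in rank order;
* score tables — ``rank  gene_id  score`` TSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression",
    "read_gct",
    "write_gct",
    "read_gene_list",
    "write_gene_list",
    "read_scores",
    "write_scores",
]


# ---------------------------------------------------------------------------
# delimited tables


def _sep_for(path: str) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def read_expression(path: str) -> ExpressionMatrix:
    """Read an expression matrix, dispatching on the file extension.

    ``.gct`` files go through the GCT v1.2 parser; anything else is read as
    a delimited table (comma for ``.csv``, tab otherwise).
    """
    if str(path).lower().endswith(".gct"):
        return read_gct(path)
    df = pd.read_csv(
        path, sep=_sep_for(path), index_col=0, float_precision="round_trip"
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix.from_frame(df)


def write_expression(X: ExpressionMatrix, path: str) -> None:
    if str(path).lower().endswith(".gct"):
        write_gct(X, path)
        return
    X.to_frame().to_csv(path, sep=_sep_for(path), index_label="gene_id")


# ---------------------------------------------------------------------------
# GCT v1.2


def read_gct(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"not a GCT v1.2 file (first line {version!r})")
        dims = fh.readline().split()
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    if list(df.columns[:2]) != ["Name", "Description"]:
        raise ValueError("GCT header must start with Name and Description")
    sample_ids = [str(c) for c in df.columns[2:]]
    if df.shape[0] != n_genes or len(sample_ids) != n_samples:
        raise ValueError(
            f"GCT dimension line says {n_genes}x{n_samples}, "
            f"table is {df.shape[0]}x{len(sample_ids)}"
        )
    values = df.iloc[:, 2:].to_numpy(dtype=np.float64)
    return ExpressionMatrix(values, [str(g) for g in df["Name"]], sample_ids)


def write_gct(X: ExpressionMatrix, path: str, descriptions=None) -> None:
    if descriptions is None:
        descriptions = ["na"] * X.n_genes
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{X.n_genes}\t{X.n_samples}\n")
        fh.write("Name\tDescription\t" + "\t".join(X.sample_ids) + "\n")
        for gid, desc, row in zip(X.gene_ids, descriptions, X.values):
            fh.write(gid + "\t" + str(desc) + "\t")
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# gene lists and score tables


def read_gene_list(path: str) -> list:
    """One gene id per line, rank order preserved, blanks skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(gene_ids, path: str) -> None:
    with open(path, "w") as fh:
        for gid in gene_ids:
            fh.write(str(gid) + "\n")


def read_scores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_scores(gene_ids, scores, path: str) -> None:
    """Write a (rank, gene_id, score) TSV; rank is 1-based."""
    df = pd.DataFrame(
        {
            "rank": np.arange(1, len(gene_ids) + 1),
            "gene_id": [str(g) for g in gene_ids],
            "score": np.asarray(scores, dtype=float),
        }
    )
    df.to_csv(path, sep="\t", index=False)
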