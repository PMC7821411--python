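"""Scoring of predicted expression: per-gene MAE and PCC, the cross-gene
permutation test, paired landmark-set comparison, and embedding clustering
quality.

For each target gene j the prediction quality across m samples is

    MAE_j = (1/m) sum_i |g_ij - ghat_ij|
    PCC_j = Pearson r(g_j, ghat_j)

A high PCC alone does not say how *uncommon* the similarity is, so the
permutation test correlates the predicted profile ghat_j against every
observed gene other than j to form a reference distribution; the p-value is
the fraction of reference correlations at least as large as the
self-correlation, and significance requires p strictly below alpha
(default 0.01).

Two landmark sets are compared by a two-sided paired t-test on the per-gene
MAE and PCC deltas over their common target genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .matrix import ExpressionMatrix

__all__ = [
    "EvaluationReport",
    "SetComparison",
    "mae_per_gene",
    "pcc_per_gene",
    "permutation_test",
    "permutation_test_all",
    "evaluate",
    "compare_landmark_sets",
    "embedding_cluster_quality",
    "read_report",
]

DEFAULT_ALPHA = 0.01


def _check_aligned(G: ExpressionMatrix, G_hat: ExpressionMatrix) -> None:
    if G.gene_ids != G_hat.gene_ids:
        raise ValueError("gene ids of observed and predicted matrices differ")
    if G.sample_ids != G_hat.sample_ids:
        raise ValueError("sample ids of observed and predicted matrices differ")


# ---------------------------------------------------------------------------
# per-gene metrics


def mae_per_gene(G: ExpressionMatrix, G_hat: ExpressionMatrix) -> np.ndarray:
    """Mean absolute error per gene across samples (expression units)."""
    _check_aligned(G, G_hat)
    return np.abs(G.values - G_hat.values).mean(axis=1)


def _standardize_rows(values: np.ndarray):
    """Rows centered and scaled to unit variance; constant rows flagged.

    Returns (Z, undefined) where constant rows of Z are zero so any dot
    product involving them yields correlation 0.
    """
    centered = values - values.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    undefined = sd == 0
    safe_sd = np.where(undefined, 1.0, sd)
    Z = centered / safe_sd[:, None]
    Z[undefined] = 0.0
    return Z, undefined


def pcc_per_gene(
    G: ExpressionMatrix, G_hat: ExpressionMatrix, with_flags: bool = False
):
    """Pearson correlation per gene between observed and predicted profiles.

    Genes constant on either side have undefined correlation; they are
    reported as 0 and flagged when ``with_flags=True``. Needs >= 3 samples.
    """
    _check_aligned(G, G_hat)
    if G.n_samples < 3:
        raise ValueError("Pearson correlation needs at least 3 samples")
    Zg, und_g = _standardize_rows(G.values)
    Zh, und_h = _standardize_rows(G_hat.values)
    r = (Zg * Zh).mean(axis=1)
    undefined = und_g | und_h
    r[undefined] = 0.0
    r = np.clip(r, -1.0, 1.0)
    if with_flags:
        return r, undefined
    return r


# ---------------------------------------------------------------------------
# permutation test


def _cross_correlations(G: ExpressionMatrix, G_hat: ExpressionMatrix):
    """R[i, j] = Pearson r(observed gene i, predicted gene j)."""
    Zg, und_g = _standardize_rows(G.values)
    Zh, und_h = _standardize_rows(G_hat.values)
    R = (Zg @ Zh.T) / G.n_samples
    return np.clip(R, -1.0, 1.0), und_g, und_h


def permutation_test(
    G: ExpressionMatrix,
    G_hat: ExpressionMatrix,
    gene,
    alpha: float = DEFAULT_ALPHA,
):
    """Cross-gene permutation test for one target gene.

    Reference distribution = { r(g_i, ghat_j) : i != j }. The p-value is the
    fraction of the reference >= r(g_j, ghat_j) (ties count against
    significance); significant iff p < alpha strictly. ``gene`` may be an id
    or a row index.
    """
    _check_aligned(G, G_hat)
    if G.n_genes < 2:
        raise ValueError("permutation test needs at least 2 genes")
    j = gene if isinstance(gene, (int, np.integer)) else G.gene_index()[str(gene)]
    p_all, sig_all = permutation_test_all(G, G_hat, alpha)
    return float(p_all[j]), bool(sig_all[j])


def permutation_test_all(
    G: ExpressionMatrix, G_hat: ExpressionMatrix, alpha: float = DEFAULT_ALPHA
):
    """Vectorized permutation test over all genes; returns (p, significant).

    Genes whose observed or predicted profile is constant are never
    significant (their correlations are undefined, reported as 0).
    """
    _check_aligned(G, G_hat)
    if G.n_genes < 2:
        raise ValueError("permutation test needs at least 2 genes")
    R, und_g, und_h = _cross_correlations(G, G_hat)
    n = G.n_genes
    self_r = np.diag(R)
    # count reference correlations >= self correlation, excluding i == j
    ge_counts = (R >= self_r[None, :]).sum(axis=0) - 1  # the diagonal ties itself
    p = ge_counts / (n - 1)
    undefined = und_g | und_h
    significant = (p < alpha) & ~undefined
    return p, significant


# ---------------------------------------------------------------------------
# reports


@dataclass
class EvaluationReport:
    """Per-target-gene metrics plus summary statistics."""

    per_gene: pd.DataFrame  # gene_id, mae, pcc, perm_p, significant
    alpha: float = DEFAULT_ALPHA

    @property
    def mean_mae(self) -> float:
        return float(self.per_gene["mae"].mean())

    @property
    def mean_pcc(self) -> float:
        return float(self.per_gene["pcc"].mean())

    @property
    def n_significant(self) -> int:
        return int(self.per_gene["significant"].sum())

    @property
    def n_genes(self) -> int:
        return len(self.per_gene)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# alpha\t{self.alpha}\n")
            fh.write(f"# mean_mae\t{self.mean_mae:.6f}\n")
            fh.write(f"# mean_pcc\t{self.mean_pcc:.6f}\n")
            fh.write(f"# n_significant\t{self.n_significant}/{self.n_genes}\n")
            self.per_gene.to_csv(fh, sep="\t", index=False)


def read_report(path: str) -> EvaluationReport:
    alpha = DEFAULT_ALPHA
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            fields = line[1:].strip().split("\t")
            if fields[0] == "alpha":
                alpha = float(fields[1])
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", dtype={"gene_id": str})
    df["significant"] = df["significant"].astype(bool)
    return EvaluationReport(per_gene=df, alpha=alpha)


def evaluate(
    G: ExpressionMatrix, G_hat: ExpressionMatrix, alpha: float = DEFAULT_ALPHA
) -> EvaluationReport:
    """Full per-gene evaluation of predictions against observations."""
    mae = mae_per_gene(G, G_hat)
    pcc, undefined = pcc_per_gene(G, G_hat, with_flags=True)
    perm_p, significant = permutation_test_all(G, G_hat, alpha)
    df = pd.DataFrame(
        {
            "gene_id": G.gene_ids,
            "mae": mae,
            "pcc": pcc,
            "perm_p": perm_p,
            "significant": significant,
            "pcc_undefined": undefined,
        }
    )
    return EvaluationReport(per_gene=df, alpha=alpha)


# ---------------------------------------------------------------------------
# paired comparison of landmark sets


@dataclass
class SetComparison:
    """Paired per-gene comparison of two evaluations over common genes."""

    per_gene: pd.DataFrame  # gene_id, mae_a, mae_b, pcc_a, pcc_b + deltas
    mae_t: float
    mae_p: float
    pcc_t: float
    pcc_p: float
    mae_wins_a: int
    mae_wins_b: int
    pcc_wins_a: int
    pcc_wins_b: int
    mae_zero_variance: bool = False
    pcc_zero_variance: bool = False

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# mae_t\t{self.mae_t}\n# mae_p\t{self.mae_p}\n")
            fh.write(f"# pcc_t\t{self.pcc_t}\n# pcc_p\t{self.pcc_p}\n")
            fh.write(
                f"# mae_wins_a\t{self.mae_wins_a}\t# mae_wins_b\t{self.mae_wins_b}\n"
            )
            fh.write(
                f"# pcc_wins_a\t{self.pcc_wins_a}\t# pcc_wins_b\t{self.pcc_wins_b}\n"
            )
            self.per_gene.to_csv(fh, sep="\t", index=False)


def _paired_t(deltas: np.ndarray):
    """Two-sided paired t-test from its closed form.

    Zero-variance deltas are degenerate: all-zero deltas give (t=0, p=1),
    constant nonzero deltas give (t=±inf, p=0) with a zero-variance flag.
    """
    n = deltas.size
    mean = deltas.mean()
    sd = deltas.std(ddof=1)
    if sd <= 1e-12 * (abs(mean) + 1.0):  # constant deltas up to round-off
        if mean == 0:
            return 0.0, 1.0, True
        return float(np.sign(mean) * np.inf), 0.0, True
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p), False


def compare_landmark_sets(
    report_a: EvaluationReport, report_b: EvaluationReport
) -> SetComparison:
    """Paired t-tests on per-gene MAE and PCC deltas over common genes."""
    a = report_a.per_gene.set_index("gene_id")
    b = report_b.per_gene.set_index("gene_id")
    common = [g for g in a.index if g in set(b.index)]
    if len(common) < 2:
        raise ValueError("need at least 2 common genes to compare")
    a = a.loc[common]
    b = b.loc[common]
    mae_delta = a["mae"].to_numpy() - b["mae"].to_numpy()
    pcc_delta = a["pcc"].to_numpy() - b["pcc"].to_numpy()
    mae_t, mae_p, mae_zv = _paired_t(mae_delta)
    pcc_t, pcc_p, pcc_zv = _paired_t(pcc_delta)
    df = pd.DataFrame(
        {
            "gene_id": common,
            "mae_a": a["mae"].to_numpy(),
            "mae_b": b["mae"].to_numpy(),
            "pcc_a": a["pcc"].to_numpy(),
            "pcc_b": b["pcc"].to_numpy(),
            "mae_delta": mae_delta,
            "pcc_delta": pcc_delta,
        }
    )
    return SetComparison(
        per_gene=df,
        mae_t=mae_t,
        mae_p=mae_p,
        pcc_t=pcc_t,
        pcc_p=pcc_p,
        mae_wins_a=int((mae_delta < 0).sum()),
        mae_wins_b=int((mae_delta > 0).sum()),
        pcc_wins_a=int((pcc_delta > 0).sum()),
        pcc_wins_b=int((pcc_delta < 0).sum()),
        mae_zero_variance=mae_zv,
        pcc_zero_variance=pcc_zv,
    )


# ---------------------------------------------------------------------------
# embedding clustering quality


def embedding_cluster_quality(embeddings: np.ndarray, labels, seed: int = 0):
    """Cluster bottleneck embeddings and score agreement with known labels.

    k-means with k = number of label classes (seeded) on the embeddings;
    returns (adjusted Rand index, mean silhouette of the induced clusters).
    """
    embeddings = np.asarray(embeddings, dtype=float)
    labels = np.asarray(labels)
    if embeddings.ndim != 2 or embeddings.shape[0] != labels.size:
        raise ValueError("embeddings must be (n_samples, n_dims) matching labels")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("need at least 2 label classes")
    km = KMeans(n_clusters=classes.size, n_init=10, random_state=seed)
    assigned = km.fit_predict(embeddings)
    ari = float(adjusted_rand_score(labels, assigned))
    sil = float(silhouette_score(embeddings, assigned))
    return ari, sil
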