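"""Evaluation metrics for benchmarking downstream inference methods.

Trajectory (R^2 of pseudotime, kNN purity), integration (graph connectivity,
batch average silhouette width), velocity (cosine similarity), classification
(AUPRC/AUROC and the AUPRC ratio over the random-classifier baseline),
Bonferroni correction, and the summary statistics used to compare simulated
with real count matrices.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

__all__ = [
    "UndefinedMetric",
    "r_squared",
    "knn_purity",
    "knn_graph",
    "graph_connectivity",
    "batch_asw",
    "velocity_cosine",
    "auprc_auroc",
    "bonferroni",
    "summary_stats",
]


class UndefinedMetric(ValueError):
    """Raised when a metric is undefined on the given input (constant
    vector, single class, single batch, ...)."""


def r_squared(pseudotime_true, pseudotime_inferred) -> float:
    """Squared Pearson correlation between true and inferred pseudotime."""
    t = np.asarray(pseudotime_true, dtype=float)
    that = np.asarray(pseudotime_inferred, dtype=float)
    if t.shape != that.shape or t.size < 2:
        raise ValueError("pseudotime vectors must have equal length >= 2")
    if t.std() == 0 or that.std() == 0:
        raise UndefinedMetric("constant pseudotime vector")
    return float(stats.pearsonr(t, that)[0] ** 2)


def knn_purity(pseudotime_true, pseudotime_inferred, k: int = 50) -> np.ndarray:
    """Per-cell Jaccard index of the k-nearest-neighbour sets (by pseudotime
    distance) under the true and the inferred ordering."""
    t = np.asarray(pseudotime_true, dtype=float)
    that = np.asarray(pseudotime_inferred, dtype=float)
    n = t.size
    if not k < n:
        raise ValueError("k must be smaller than the number of cells")

    def knn_sets(v):
        d = np.abs(v[:, None] - v[None, :])
        np.fill_diagonal(d, np.inf)
        return np.argsort(d, axis=1, kind="stable")[:, :k]

    a, b = knn_sets(t), knn_sets(that)
    out = np.empty(n)
    for i in range(n):
        sa, sb = set(a[i]), set(b[i])
        out[i] = len(sa & sb) / len(sa | sb)
    return out


def knn_graph(embedding: np.ndarray, k: int = 15) -> sparse.csr_matrix:
    """Symmetrised kNN adjacency over cells (Euclidean)."""
    from sklearn.neighbors import kneighbors_graph

    g = kneighbors_graph(embedding, n_neighbors=min(k, len(embedding) - 1))
    return ((g + g.T) > 0).astype(int)


def graph_connectivity(adjacency, cell_types) -> float:
    """Mean over types of |largest connected component within the type| /
    |type| on the type-induced subgraph."""
    adj = sparse.csr_matrix(adjacency)
    types = np.asarray(cell_types)
    scores = []
    for t in pd.unique(types):
        idx = np.where(types == t)[0]
        if len(idx) == 0:
            warnings.warn(f"empty cell type {t!r} excluded", stacklevel=2)
            continue
        sub = adj[np.ix_(idx, idx)]
        _, labels = connected_components(sub, directed=False)
        largest = np.bincount(labels).max()
        scores.append(largest / len(idx))
    return float(np.mean(scores))


def batch_asw(embedding: np.ndarray, batch_labels, cell_types) -> float:
    """Batch-mixing score: per cell type, mean of ``1 - |silhouette|``
    computed on batch labels, averaged over types (1 = perfectly mixed)."""
    from sklearn.metrics import silhouette_samples

    batches = np.asarray(batch_labels)
    types = np.asarray(cell_types)
    if len(np.unique(batches)) < 2:
        raise UndefinedMetric("batch ASW needs at least two batches")
    scores = []
    for t in pd.unique(types):
        idx = np.where(types == t)[0]
        sub_b = batches[idx]
        if len(np.unique(sub_b)) < 2 or len(idx) < 3:
            warnings.warn(f"type {t!r} skipped (fewer than two batches)",
                          stacklevel=2)
            continue
        sil = silhouette_samples(np.asarray(embedding)[idx], sub_b)
        scores.append(float(np.mean(1.0 - np.abs(sil))))
    if not scores:
        raise UndefinedMetric("no cell type had two batches")
    return float(np.mean(scores))


def velocity_cosine(v_true: np.ndarray, v_inferred: np.ndarray) -> float:
    """Mean per-cell cosine similarity between true and inferred velocity;
    zero-norm rows are skipped (with a warning reporting the count)."""
    v = np.asarray(v_true, dtype=float)
    u = np.asarray(v_inferred, dtype=float)
    if v.shape != u.shape:
        raise ValueError("velocity matrices must have equal shapes")
    nv = np.linalg.norm(v, axis=1)
    nu = np.linalg.norm(u, axis=1)
    ok = (nv > 0) & (nu > 0)
    skipped = int((~ok).sum())
    if skipped:
        warnings.warn(f"{skipped} zero-norm velocity rows skipped", stacklevel=2)
    if not ok.any():
        raise UndefinedMetric("all velocity rows have zero norm")
    cos = (v[ok] * u[ok]).sum(axis=1) / (nv[ok] * nu[ok])
    return float(cos.mean())


def auprc_auroc(truth_binary, scores) -> tuple[float, float, float]:
    """AUPRC, AUROC and the AUPRC ratio (AUPRC / positive prevalence, the
    random-classifier baseline)."""
    from sklearn.metrics import average_precision_score, roc_auc_score

    y = np.asarray(truth_binary).astype(int).ravel()
    p = np.asarray(scores, dtype=float).ravel()
    if len(np.unique(y)) < 2:
        raise UndefinedMetric("both classes must be present")
    auprc = float(average_precision_score(y, p))
    auroc = float(roc_auc_score(y, p))
    prevalence = y.mean()
    return auprc, auroc, auprc / prevalence


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni-adjusted p-values: ``min(p_i * n, 1)``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


def summary_stats(counts: np.ndarray, modality: str = "rna") -> dict:
    """Summary statistics comparing simulated with real data.

    RNA: library size and zero proportion per cell; zero proportion, mean and
    variance per gene; plus the per-gene (zero proportion, mean) pairing.
    ATAC: library size and sparsity per cell, mean per peak.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    if modality == "atac":
        return {
            "lib_size_per_cell": x.sum(axis=1),
            "cell_sparsity": (x == 0).mean(axis=1),
            "peak_mean": x.mean(axis=0),
        }
    return {
        "lib_size_per_cell": x.sum(axis=1),
        "zero_prop_per_cell": (x == 0).mean(axis=1),
        "zero_prop_per_gene": (x == 0).mean(axis=0),
        "mean_per_gene": x.mean(axis=0),
        "var_per_gene": x.var(axis=0),
        "zero_vs_mean": np.column_stack([(x == 0).mean(axis=0), x.mean(axis=0)]),
    }
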