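"""Embedding, classification, and regression evaluation metrics.

Biological conservation: Isolated Label Score (ISO), Normalized Mutual
Information (NMI), cell-type Average Silhouette Width (cASW), and
cell-type Local Inverse Simpson Index (cLISI).  Batch integration: batch
Average Silhouette Width (bASW) and Graph Connectivity (GC).  All are
scaled to [0, 1] with higher better.  Conventions follow the single-cell
integration benchmarking (scIB) literature:

* NMI is computed against a clustering of the embedding — Leiden with
  the resolution swept and NMI maximized by default, or k-means with
  k = number of cell types as a deterministic small-data fallback;
* cASW = (mean silhouette over cell-type labels + 1) / 2;
* cLISI averages per-cell ``(n_types - LISI_i) / (n_types - 1)`` where
  ``LISI_i`` is the inverse Simpson index of cell-type composition among
  the k nearest neighbors (1 at perfect separation);
* ISO takes the label(s) present in the fewest batches and reports the
  best label-vs-rest silhouette, rescaled to [0, 1];
* bASW averages, over cell types, ``mean(1 - |silhouette w.r.t. batch|)``
  within the type (a type confined to one batch contributes 1);
* GC averages, over cell types, the fraction of the type's cells in the
  largest connected component of the type's induced kNN subgraph.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr, spearmanr
from sklearn.decomposition import PCA
from sklearn.cluster import KMeans
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    normalized_mutual_info_score,
    roc_auc_score,
    silhouette_samples,
    silhouette_score,
)
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "knn_graph",
    "clustering_nmi",
    "leiden_nmi_clustering",
    "bio_conservation_metrics",
    "batch_integration_metrics",
    "classification_metrics",
    "regression_metrics",
    "pca_baseline",
]


def knn_graph(embeddings: np.ndarray, k: int = 15) -> sp.csr_matrix:
    """Euclidean kNN adjacency (no self-loops), symmetrized by union."""
    n = embeddings.shape[0]
    k = min(k, n - 1)
    # kneighbors_graph on the fitted data excludes each point from its own
    # neighborhood, so rows have exactly k real neighbors
    nn = NearestNeighbors(n_neighbors=k).fit(embeddings)
    adj = sp.csr_matrix(nn.kneighbors_graph(mode="connectivity"))
    sym = adj.maximum(adj.T)
    return sp.csr_matrix(sym)


def _knn_indices(embeddings: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k nearest neighbors of each cell, self excluded."""
    n = embeddings.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(embeddings)
    return nn.kneighbors(return_distance=False)


def leiden_nmi_clustering(embeddings: np.ndarray, labels: np.ndarray,
                          k: int = 15, resolutions=None,
                          seed: int = 0) -> np.ndarray:
    """Leiden clustering of the kNN graph, resolution chosen to maximize NMI."""
    import igraph
    import leidenalg

    adj = knn_graph(embeddings, k=k).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = igraph.Graph(n=embeddings.shape[0], edges=edges)
    if resolutions is None:
        resolutions = np.arange(0.1, 2.01, 0.1)
    best, best_nmi = None, -1.0
    for res in resolutions:
        part = leidenalg.find_partition(
            graph, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(res), seed=seed)
        membership = np.asarray(part.membership)
        nmi = normalized_mutual_info_score(labels, membership)
        if nmi > best_nmi:
            best, best_nmi = membership, nmi
    return best


def clustering_nmi(labels_true, labels_pred) -> float:
    """Normalized mutual information (arithmetic normalization)."""
    return float(normalized_mutual_info_score(labels_true, labels_pred))


def _lisi_scores(neighbor_labels: np.ndarray) -> np.ndarray:
    """Inverse Simpson index per cell from its neighbors' labels."""
    out = np.zeros(neighbor_labels.shape[0])
    for i, row in enumerate(neighbor_labels):
        _, counts = np.unique(row, return_counts=True)
        p = counts / counts.sum()
        out[i] = 1.0 / np.sum(p * p)
    return out


def bio_conservation_metrics(embeddings: np.ndarray, cell_type_labels,
                             batch_labels, k: int = 15,
                             clustering: str = "leiden",
                             seed: int = 0) -> dict[str, float]:
    """ISO, NMI, cASW, cLISI on an embedding (all in [0,1], higher better)."""
    y = np.asarray(cell_type_labels)
    b = np.asarray(batch_labels)
    types = np.unique(y)
    if len(types) < 2:
        raise ValueError("bio-conservation metrics need at least 2 cell types")
    if k >= embeddings.shape[0]:
        raise ValueError("k must be smaller than the number of cells")

    if clustering == "leiden":
        clusters = leiden_nmi_clustering(embeddings, y, k=k, seed=seed)
    elif clustering == "kmeans":
        clusters = KMeans(n_clusters=len(types), n_init=10,
                          random_state=seed).fit_predict(embeddings)
    else:
        raise ValueError(f"unknown clustering {clustering!r}")
    nmi = float(normalized_mutual_info_score(y, clusters))

    casw = float((silhouette_score(embeddings, y) + 1.0) / 2.0)

    neigh = _knn_indices(embeddings, k)
    lisi = _lisi_scores(y[neigh])
    clisi = float(np.mean((len(types) - lisi) / (len(types) - 1))) if len(types) > 1 else 1.0

    # isolated labels: present in the fewest batches
    n_batches_per_type = {t: len(np.unique(b[y == t])) for t in types}
    fewest = min(n_batches_per_type.values())
    isolated = [t for t in types if n_batches_per_type[t] == fewest]
    iso_scores = []
    for t in isolated:
        binary = (y == t).astype(int)
        s = silhouette_samples(embeddings, binary)
        iso_scores.append((np.mean(s[binary == 1]) + 1.0) / 2.0)
    iso = float(max(iso_scores))

    return {"ISO": iso, "NMI": nmi, "cASW": casw, "cLISI": clisi}


def batch_integration_metrics(embeddings: np.ndarray, cell_type_labels,
                              batch_labels, k: int = 15) -> dict[str, float]:
    """bASW and GC on an embedding (both in [0,1], higher better)."""
    y = np.asarray(cell_type_labels)
    b = np.asarray(batch_labels)
    if len(np.unique(b)) < 2:
        raise ValueError("batch-integration metrics need at least 2 batches")
    adj = knn_graph(embeddings, k=k)

    basw_terms, gc_terms = [], []
    for t in np.unique(y):
        idx = np.flatnonzero(y == t)
        batches_here = np.unique(b[idx])
        if len(batches_here) < 2 or len(idx) <= len(batches_here):
            logger.info("cell type %s confined to one batch; bASW term = 1", t)
            basw_terms.append(1.0)
        else:
            s = silhouette_samples(embeddings[idx], b[idx])
            basw_terms.append(float(np.mean(1.0 - np.abs(s))))
        sub = adj[idx][:, idx]
        n_comp, comp = connected_components(sub, directed=False)
        largest = np.bincount(comp).max()
        gc_terms.append(largest / len(idx))
    return {"bASW": float(np.mean(basw_terms)), "GC": float(np.mean(gc_terms))}


def classification_metrics(true_labels, score_matrix) -> dict[str, float]:
    """ACC, MacroF1, MicroF1, and one-vs-rest macro ROC-AUC from soft scores."""
    y = np.asarray(true_labels)
    scores = np.asarray(score_matrix, dtype=float)
    if scores.ndim != 2:
        raise ValueError("score_matrix must be 2-D (cells x classes)")
    if not np.allclose(scores.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("score rows must sum to 1")
    pred = scores.argmax(axis=1)
    present = np.unique(y)
    if len(present) < scores.shape[1]:
        warnings.warn("classes absent from truth are excluded from macro averages")
    acc = float(accuracy_score(y, pred))
    macro = float(f1_score(y, pred, labels=present, average="macro"))
    micro = float(f1_score(y, pred, average="micro"))
    aucs = []
    for c in present:
        if len(np.unique(y == c)) == 2:
            aucs.append(roc_auc_score((y == c).astype(int), scores[:, c]))
    auroc = float(np.mean(aucs)) if aucs else float("nan")
    return {"ACC": acc, "MacroF1": macro, "MicroF1": micro, "ROC-AUC": auroc}


def regression_metrics(true_values, predicted_values) -> dict[str, float]:
    """MSE, Spearman (SRCC), and Pearson (PRCC), flattened over all pairs.

    Correlations on zero-variance input are undefined and returned as NaN.
    """
    t = np.asarray(true_values, dtype=float).ravel()
    p = np.asarray(predicted_values, dtype=float).ravel()
    if t.shape != p.shape or t.size < 2:
        raise ValueError("inputs must have equal length >= 2")
    mse = float(np.mean((t - p) ** 2))
    if np.std(t) == 0 or np.std(p) == 0:
        return {"MSE": mse, "SRCC": float("nan"), "PRCC": float("nan")}
    srcc = float(spearmanr(t, p).statistic)
    prcc = float(pearsonr(t, p).statistic)
    return {"MSE": mse, "SRCC": srcc, "PRCC": prcc}


def pca_baseline(binary_accessibility, n_components: int = 50,
                 seed: int = 0) -> np.ndarray:
    """Centered PCA scores of the binary accessibility matrix.

    The trivial embedding baseline; deterministic up to component sign.
    """
    X = binary_accessibility.toarray() if sp.issparse(binary_accessibility) \
        else np.asarray(binary_accessibility, dtype=float)
    n_components = min(n_components, min(X.shape) - 1)
    return PCA(n_components=n_components, svd_solver="full",
               random_state=seed).fit_transform(X)
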