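"""Brute-force reference implementations used only by the test suite.

Every function here is written as a direct transcription of the metric
definition — loops, no library calls — and is deliberately independent
of the implementations in ``peakgene.metrics``.
"""

from __future__ import annotations

import math

import numpy as np


def nmi_oracle(a, b) -> float:
    """NMI from the contingency table, arithmetic normalization."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ua, ub = np.unique(a), np.unique(b)
    mi = 0.0
    for x in ua:
        for y in ub:
            pxy = np.sum((a == x) & (b == y)) / n
            if pxy > 0:
                px, py = np.sum(a == x) / n, np.sum(b == y) / n
                mi += pxy * math.log(pxy / (px * py))

    def entropy(v, uv):
        h = 0.0
        for x in uv:
            p = np.sum(v == x) / n
            if p > 0:
                h -= p * math.log(p)
        return h

    ha, hb = entropy(a, ua), entropy(b, ub)
    denom = (ha + hb) / 2
    return mi / denom if denom > 0 else 1.0


def silhouette_oracle(X, labels) -> np.ndarray:
    """Per-sample silhouette widths by explicit distance loops."""
    X, labels = np.asarray(X, dtype=float), np.asarray(labels)
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i][own].sum() / (n_own - 1)
        b = min(D[i][labels == c].mean() for c in np.unique(labels) if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


def knn_oracle(X, k) -> list[set[int]]:
    """k nearest neighbors per point (self excluded), by full sort."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    k = min(k, n - 1)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    out = []
    for i in range(n):
        order = [j for j in np.argsort(D[i], kind="stable") if j != i]
        out.append(set(order[:k]))
    return out


def clisi_oracle(X, labels, k) -> float:
    """Mean scaled cell-type LISI over cells, kNN neighborhoods."""
    labels = np.asarray(labels)
    n_types = len(np.unique(labels))
    neigh = knn_oracle(X, k)
    vals = []
    for i in range(len(labels)):
        lab = labels[list(neigh[i])]
        simpson = 0.0
        for c in np.unique(lab):
            p = np.mean(lab == c)
            simpson += p * p
        vals.append((n_types - 1.0 / simpson) / (n_types - 1))
    return float(np.mean(vals))


def gc_oracle(X, type_labels, k) -> float:
    """Graph connectivity by BFS on the union-symmetrized kNN graph."""
    type_labels = np.asarray(type_labels)
    neigh = knn_oracle(X, k)
    n = len(type_labels)
    adj = [set() for _ in range(n)]
    for i in range(n):
        for j in neigh[i]:
            adj[i].add(j)
            adj[j].add(i)
    terms = []
    for t in np.unique(type_labels):
        members = list(np.flatnonzero(type_labels == t))
        member_set = set(members)
        seen: set[int] = set()
        best = 0
        for start in members:
            if start in seen:
                continue
            comp = {start}
            frontier = [start]
            while frontier:
                u = frontier.pop()
                for v in adj[u]:
                    if v in member_set and v not in comp:
                        comp.add(v)
                        frontier.append(v)
            seen |= comp
            best = max(best, len(comp))
        terms.append(best / len(members))
    return float(np.mean(terms))


def basw_oracle(X, type_labels, batch_labels) -> float:
    """Batch ASW: mean over types of mean(1 - |silhouette wrt batch|)."""
    type_labels = np.asarray(type_labels)
    batch_labels = np.asarray(batch_labels)
    terms = []
    for t in np.unique(type_labels):
        idx = np.flatnonzero(type_labels == t)
        batches = np.unique(batch_labels[idx])
        if len(batches) < 2 or len(idx) <= len(batches):
            terms.append(1.0)
            continue
        s = silhouette_oracle(np.asarray(X)[idx], batch_labels[idx])
        terms.append(float(np.mean(1 - np.abs(s))))
    return float(np.mean(terms))


def gene_activity_oracle(counts, peaks, genes, upstream) -> np.ndarray:
    """All-pairs interval-overlap loop."""
    counts = np.asarray(counts)
    out = np.zeros((len(genes), counts.shape[0]))
    for gi, gene in enumerate(genes.itertuples(index=False)):
        if gene.strand == "+":
            lo, hi = gene.body_start - upstream, gene.body_end
        else:
            lo, hi = gene.body_start, gene.body_end + upstream
        for pi, peak in enumerate(peaks.itertuples(index=False)):
            if peak.chrom == gene.chrom and peak.start < hi and peak.end > lo:
                out[gi] += counts[:, pi]
    return out
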