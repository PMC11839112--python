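"""Gene Activity baseline: summed accessibility near each gene.

The classic Signac-style predictor of expression from ATAC alone: for
each gene, sum the counts of every peak overlapping the gene body
extended ``upstream_window`` bases upstream of the TSS (strand-aware).
All intervals are 0-based half-open; overlap means any shared base.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["gene_activity"]


def gene_activity(counts, peaks: pd.DataFrame, genes: pd.DataFrame,
                  upstream_window: int = 2000) -> np.ndarray:
    """Genes x cells activity matrix from peak counts.

    Parameters
    ----------
    counts : cells x peaks matrix (raw or binarized accessibility).
    peaks : DataFrame with ``chrom``, ``start``, ``end``.
    genes : DataFrame with ``chrom``, ``strand``, ``body_start``, ``body_end``.
    upstream_window : bases added upstream of the TSS (default 2,000).

    A gene on a chromosome with no peaks yields a zero row.  Activity is
    additive in peak counts: doubling a peak's counts doubles its
    contribution to every gene it overlaps.
    """
    if upstream_window < 0:
        raise ValueError("upstream_window must be >= 0")
    counts = sp.csc_matrix(counts)
    n_cells = counts.shape[0]
    if counts.shape[1] != len(peaks):
        raise ValueError(f"{counts.shape[1]} peak columns but {len(peaks)} peak rows")

    by_chrom: dict[str, np.ndarray] = {
        c: np.flatnonzero((peaks["chrom"] == c).to_numpy())
        for c in peaks["chrom"].unique()
    }
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()

    out = np.zeros((len(genes), n_cells))
    for gi, gene in enumerate(genes.itertuples(index=False)):
        idx = by_chrom.get(gene.chrom)
        if idx is None:
            continue
        if gene.strand == "+":
            lo, hi = gene.body_start - upstream_window, gene.body_end
        elif gene.strand == "-":
            lo, hi = gene.body_start, gene.body_end + upstream_window
        else:
            raise ValueError(f"gene row {gi}: bad strand {gene.strand!r}")
        hits = idx[(starts[idx] < hi) & (ends[idx] > lo)]
        if hits.size:
            out[gi] = np.asarray(counts[:, hits].sum(axis=1)).ravel()
    return out
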