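"""Paired multiome (scATAC + scRNA) I/O, binarization, and expression binning.

On-disk layout follows the single-cell convention: Matrix Market matrices
are features x cells (peaks x cells for ATAC, genes x cells for RNA) and
are transposed to cells x features in memory.  Peaks travel as BED3+
(0-based, half-open), genes as a TSV with chromosome, TSS, strand and
body interval, cells as a TSV with ``cell_id``, ``batch`` and an optional
``cell_type`` column.  All readers are gzip-transparent.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "MultiomeDataset",
    "load_multiome",
    "write_multiome",
    "binarize_accessibility",
    "binarize_expression",
    "bin_expression",
]

_STRANDS = {"+", "-"}


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_mtx(path) -> sp.csr_matrix:
    with _open_text(path) as fh:
        return sp.csr_matrix(scipy.io.mmread(fh))


def _check_chrom(name: str, source: str, row: int) -> None:
    if not name or any(c.isspace() for c in str(name)):
        raise ValueError(f"{source}: unrecognized chromosome name {name!r} at row {row}")


@dataclass
class MultiomeDataset:
    """Paired binarized accessibility and expression with cell metadata.

    Matrices are cells x features.  ``accessibility`` is the binary matrix
    the model consumes; ``expression_binary`` the pre-training target;
    ``expression_binned`` the ordinal fine-tuning target.
    """

    accessibility_raw: sp.csr_matrix
    accessibility: sp.csr_matrix
    expression_raw: sp.csr_matrix
    expression_binary: sp.csr_matrix
    expression_binned: np.ndarray
    cell_ids: list[str]
    batch_labels: np.ndarray
    peaks: pd.DataFrame          # peak_id, chrom, start, end
    genes: pd.DataFrame          # gene_id, chrom, tss, strand, body_start, body_end
    batch_names: list[str]
    cell_type_labels: np.ndarray | None = None
    cell_type_names: list[str] | None = None
    n_bins: int = 10
    extras: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.accessibility.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.accessibility.shape[1]

    @property
    def n_genes(self) -> int:
        return self.expression_raw.shape[1]

    @property
    def n_batches(self) -> int:
        return len(self.batch_names)

    def validate(self) -> None:
        n = self.n_cells
        for name, mat in [
            ("accessibility_raw", self.accessibility_raw),
            ("expression_raw", self.expression_raw),
            ("expression_binary", self.expression_binary),
        ]:
            if mat.shape[0] != n:
                raise ValueError(f"{name} has {mat.shape[0]} cells, expected {n}")
        if self.expression_binned.shape != self.expression_raw.shape:
            raise ValueError("expression_binned shape mismatch")
        if len(self.cell_ids) != n or len(self.batch_labels) != n:
            raise ValueError("cell metadata length mismatch")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        uniq = np.unique(self.batch_labels)
        if uniq.min() < 0 or uniq.max() >= len(self.batch_names):
            raise ValueError("batch labels not dense in [0, n_batches)")
        acc = self.accessibility
        if acc.nnz and not np.all(acc.data == 1):
            raise ValueError("accessibility is not binary")


def binarize_accessibility(raw: sp.spmatrix) -> sp.csr_matrix:
    """Binary accessibility: 1 wherever the raw fragment count is positive."""
    raw = sp.csr_matrix(raw)
    if raw.nnz and raw.data.min() < 0:
        raise ValueError("accessibility counts must be non-negative")
    out = raw.copy()
    out.data = np.ones_like(out.data)
    out.eliminate_zeros()
    return out


def binarize_expression(raw: sp.spmatrix) -> sp.csr_matrix:
    """Binary expression indicator: 1 wherever the raw count is positive."""
    raw = sp.csr_matrix(raw)
    if raw.nnz and raw.data.min() < 0:
        raise ValueError("expression counts must be non-negative")
    out = raw.copy()
    out.data = np.ones_like(out.data)
    out.eliminate_zeros()
    return out


def bin_expression(raw, n_bins: int = 10, target_sum: float = 1e4) -> np.ndarray:
    """Discretize expression into ``n_bins`` ordered levels per cell.

    Zeros map to bin 0.  Non-zero values are library-size normalized to
    ``target_sum``, log1p-transformed, and assigned to bins
    ``1..n_bins-1`` by within-cell quantiles of the non-zero values.
    Equal raw values always land in the same bin, and binning is monotone
    in the raw value; multiplying a cell's row by a positive constant
    leaves the bins unchanged (the normalization cancels).

    Accepts a single row (1-D) or a cells x genes matrix (2-D or sparse).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    arr = raw.toarray() if sp.issparse(raw) else np.asarray(raw, dtype=float)
    single = arr.ndim == 1
    if single:
        arr = arr[None, :]
    if arr.size and arr.min() < 0:
        raise ValueError("expression values must be non-negative")
    out = np.zeros(arr.shape, dtype=np.int64)
    for i in range(arr.shape[0]):
        row = arr[i]
        nz = row > 0
        if not nz.any():
            continue
        vals = np.log1p(row[nz] / row.sum() * target_sum)
        edges = np.quantile(vals, np.linspace(0, 1, n_bins))
        out[i, nz] = np.digitize(vals, edges[1:-1], right=True) + 1
    return out[0] if single else out


def _read_cell_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "batch": str})
    for col in ("cell_id", "batch"):
        if col not in meta.columns:
            raise ValueError(f"{path}: cell metadata missing required column {col!r}")
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"{path}: duplicate cell id {dup!r}")
    return meta


def load_multiome(atac_matrix_path, peak_bed_path, rna_matrix_path,
                  gene_table_path, cell_metadata_path,
                  n_bins: int = 10) -> MultiomeDataset:
    """Load a paired multiome from standard files and derive all matrices.

    Axis order is preserved exactly as on disk; batch names are mapped to
    dense integer codes in order of first appearance.
    """
    atac = _read_mtx(atac_matrix_path).T.tocsr()       # -> cells x peaks
    rna = _read_mtx(rna_matrix_path).T.tocsr()         # -> cells x genes

    peaks = pd.read_csv(peak_bed_path, sep="\t", header=None, comment="#")
    if peaks.shape[1] < 3:
        raise ValueError(f"{peak_bed_path}: BED needs at least 3 columns")
    peaks = peaks.iloc[:, :4] if peaks.shape[1] >= 4 else peaks.iloc[:, :3]
    peaks.columns = ["chrom", "start", "end", "name"][: peaks.shape[1]]
    for i, row in enumerate(peaks.itertuples(index=False)):
        _check_chrom(row.chrom, str(peak_bed_path), i)
        if not row.start < row.end:
            raise ValueError(f"{peak_bed_path}: row {i} has start >= end")
    if "name" not in peaks.columns:
        peaks["name"] = [f"{c}:{s}-{e}" for c, s, e in
                         zip(peaks["chrom"], peaks["start"], peaks["end"])]
    peaks = peaks.rename(columns={"name": "peak_id"})[["peak_id", "chrom", "start", "end"]]

    genes = pd.read_csv(gene_table_path, sep="\t")
    required = {"gene_id", "chrom", "tss", "strand", "body_start", "body_end"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"{gene_table_path}: missing columns {sorted(missing)}")
    for i, row in enumerate(genes.itertuples(index=False)):
        _check_chrom(row.chrom, str(gene_table_path), i)
        if row.strand not in _STRANDS:
            raise ValueError(f"{gene_table_path}: row {i} has strand {row.strand!r}")

    meta = _read_cell_metadata(cell_metadata_path)

    if atac.shape[1] != len(peaks):
        raise ValueError(
            f"{atac_matrix_path}: {atac.shape[1]} peaks in matrix but "
            f"{len(peaks)} rows in {peak_bed_path}")
    if rna.shape[1] != len(genes):
        raise ValueError(
            f"{rna_matrix_path}: {rna.shape[1]} genes in matrix but "
            f"{len(genes)} rows in {gene_table_path}")
    if atac.shape[0] != len(meta):
        raise ValueError(
            f"cell-count mismatch: {atac.shape[0]} cells in {atac_matrix_path} "
            f"but {len(meta)} rows in {cell_metadata_path}")
    if rna.shape[0] != atac.shape[0]:
        raise ValueError(
            f"cell-count mismatch: {atac.shape[0]} cells in {atac_matrix_path} "
            f"but {rna.shape[0]} in {rna_matrix_path}")

    batch_names = list(pd.unique(meta["batch"]))
    batch_labels = meta["batch"].map({b: i for i, b in enumerate(batch_names)}).to_numpy()

    cell_type_labels = None
    cell_type_names = None
    if "cell_type" in meta.columns and meta["cell_type"].notna().all():
        cell_type_names = list(pd.unique(meta["cell_type"]))
        cell_type_labels = meta["cell_type"].map(
            {t: i for i, t in enumerate(cell_type_names)}).to_numpy()

    ds = MultiomeDataset(
        accessibility_raw=atac,
        accessibility=binarize_accessibility(atac),
        expression_raw=rna,
        expression_binary=binarize_expression(rna),
        expression_binned=bin_expression(rna, n_bins=n_bins),
        cell_ids=meta["cell_id"].tolist(),
        batch_labels=batch_labels,
        peaks=peaks.reset_index(drop=True),
        genes=genes.reset_index(drop=True),
        batch_names=batch_names,
        cell_type_labels=cell_type_labels,
        cell_type_names=cell_type_names,
        n_bins=n_bins,
    )
    ds.validate()
    return ds


def write_multiome(dataset: MultiomeDataset, out_dir, force: bool = False) -> dict[str, Path]:
    """Write the raw matrices and annotation tables in loadable form.

    Returns a dict of the paths written; ``load_multiome`` on them
    round-trips every matrix and label exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    existing = list(out.iterdir())
    if existing and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")

    paths = {
        "atac": out / "atac.mtx",
        "peaks": out / "peaks.bed",
        "rna": out / "rna.mtx",
        "genes": out / "genes.tsv",
        "cells": out / "cells.tsv",
    }
    scipy.io.mmwrite(str(paths["atac"]), dataset.accessibility_raw.T.tocoo(),
                     field="integer" if np.issubdtype(dataset.accessibility_raw.dtype, np.integer) else "real")
    scipy.io.mmwrite(str(paths["rna"]), dataset.expression_raw.T.tocoo(),
                     field="integer" if np.issubdtype(dataset.expression_raw.dtype, np.integer) else "real",
                     precision=17)
    dataset.peaks[["chrom", "start", "end", "peak_id"]].to_csv(
        paths["peaks"], sep="\t", header=False, index=False)
    dataset.genes.to_csv(paths["genes"], sep="\t", index=False)
    meta = pd.DataFrame({
        "cell_id": dataset.cell_ids,
        "batch": [dataset.batch_names[b] for b in dataset.batch_labels],
    })
    if dataset.cell_type_labels is not None:
        meta["cell_type"] = [dataset.cell_type_names[t] for t in dataset.cell_type_labels]
    meta.to_csv(paths["cells"], sep="\t", index=False)
    return paths
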