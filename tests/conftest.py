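"""Shared fixtures: tiny on-disk multiome files and simulated datasets.

Everything is generated programmatically; the expensive pre-trained
encoder used by the acceptance tests is session-scoped so its cost is
paid once.
"""

from __future__ import annotations

import numpy as np
import pytest
import scipy.io
import scipy.sparse as sp

import peakgene as pg


@pytest.fixture
def tiny_files(tmp_path):
    """3 cells x 4 peaks / 3 cells x 2 genes written as MTX/BED/TSV."""
    atac = sp.csr_matrix(np.array([[0, 3, 1, 0],
                                   [1, 0, 0, 2],
                                   [0, 0, 5, 0]]))
    rna = sp.csr_matrix(np.array([[2, 0],
                                  [0, 1],
                                  [4, 7]]))
    scipy.io.mmwrite(str(tmp_path / "atac.mtx"), atac.T.tocoo(), field="integer")
    scipy.io.mmwrite(str(tmp_path / "rna.mtx"), rna.T.tocoo(), field="integer")
    (tmp_path / "peaks.bed").write_text(
        "chr1\t100\t300\tp1\nchr1\t500\t700\tp2\nchr2\t100\t250\tp3\nchr2\t400\t600\tp4\n")
    (tmp_path / "genes.tsv").write_text(
        "gene_id\tchrom\ttss\tstrand\tbody_start\tbody_end\n"
        "gA\tchr1\t1000\t+\t1000\t2000\n"
        "gB\tchr2\t1500\t-\t900\t1501\n")
    (tmp_path / "cells.tsv").write_text(
        "cell_id\tbatch\tcell_type\nc1\tb1\tT\nc2\tb2\tT\nc3\tb1\tB\n")
    return tmp_path


@pytest.fixture(scope="session")
def small_sim():
    """A 60-cell dataset for fast unit tests."""
    cfg = pg.SimulationConfig(n_cells=60, n_peaks=80, n_genes=30,
                              peaks_per_program=20, genes_per_program=9,
                              regulatory_peaks_per_gene=5, seed=7)
    return pg.generate(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """The desk-scale study dataset: 600 cells, 3 types, 2 batches."""
    return pg.generate(pg.SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pretrained_encoder(study_sim):
    """30-epoch pre-trained encoder on the study dataset (shared)."""
    dataset, _ = study_sim
    enc = pg.PeakToGeneEncoder(epochs=30, random_state=0)
    enc.fit(dataset)
    return enc
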