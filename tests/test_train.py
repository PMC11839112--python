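"""Training loops: balanced gene sampling, optimization sanity, determinism."""

import numpy as np
import pytest

import peakgene as pg
from peakgene.model import ModelConfig, PeakSetModel
from peakgene.train import (
    FinetuneConfig,
    PretrainConfig,
    extract_cell_embeddings,
    finetune_celltype,
    finetune_expression,
    pretrain,
    sample_balanced_genes,
)
from peakgene.vocab import PeakVocabulary


def tiny_model(ds, **kw):
    vocab = PeakVocabulary.from_annotation(ds.peaks)
    cfg = dict(n_peaks=vocab.n_peaks, n_chroms=vocab.n_chroms, n_genes=ds.n_genes,
               n_batches=ds.n_batches, d_model=16, n_layers=1, n_heads=2,
               ff_mult=2, seed=0)
    cfg.update(kw)
    return PeakSetModel(ModelConfig(**cfg)), vocab


class TestBalancedSampler:
    def test_exact_fifty_fifty_when_feasible(self):
        row = np.zeros(100)
        row[:40] = 1
        genes, targets = sample_balanced_genes(row, 40, rng=0)
        assert len(genes) == 40
        assert targets.sum() == 20
        assert np.array_equal(np.sort(targets), np.r_[np.zeros(20), np.ones(20)])
        assert len(set(genes)) == 40

    def test_limited_by_minority_class(self):
        row = np.zeros(100)
        row[:5] = 1
        genes, targets = sample_balanced_genes(row, 80, rng=1)
        assert len(genes) == 10 and targets.sum() == 5

    def test_targets_align_with_row_values(self):
        rng = np.random.default_rng(2)
        row = (rng.random(60) < 0.3).astype(float)
        genes, targets = sample_balanced_genes(row, 20, rng=3)
        assert np.array_equal(row[genes], targets)

    def test_degenerate_single_class_row_warns(self, caplog):
        genes, targets = sample_balanced_genes(np.ones(10), 8, rng=0)
        assert len(genes) == 4 and targets.all()

    def test_odd_l_gene_rejected(self):
        with pytest.raises(ValueError):
            sample_balanced_genes(np.ones(10), 7)

    def test_deterministic_given_seed(self):
        row = np.zeros(50)
        row[::2] = 1
        a = sample_balanced_genes(row, 30, rng=9)
        b = sample_balanced_genes(row, 30, rng=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_expressed_genes_sampled_uniformly(self):
        row = np.zeros(30)
        row[:20] = 1
        counts = np.zeros(20)
        n = 800
        for s in range(n):
            genes, targets = sample_balanced_genes(row, 20, rng=s)
            counts[genes[targets == 1]] += 1
        p = 10 / 20
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(counts / n - p) < 3.5 * se)


class TestPretrain:
    def test_loss_decreases_and_auroc_logged(self, small_sim):
        ds, _ = small_sim
        model, vocab = tiny_model(ds)
        cfg = PretrainConfig(l_gene=16, epochs=5, batch_size=16, grad_accum=1,
                             lr=2e-3, seed=0, max_peaks=64, val_fraction=0.2)
        log = pretrain(ds, model, vocab, cfg)
        losses = log.losses()
        assert losses[-1] < losses[0]
        assert "val_auroc" in log.records[-1]

    def test_bit_reproducible_loss_curves(self, small_sim):
        ds, _ = small_sim
        curves = []
        for _ in range(2):
            model, vocab = tiny_model(ds)
            cfg = PretrainConfig(l_gene=16, epochs=3, batch_size=16, grad_accum=1,
                                 lr=2e-3, seed=11, max_peaks=64, val_fraction=0.2)
            curves.append(pretrain(ds, model, vocab, cfg).losses())
        assert curves[0] == curves[1]


class TestFinetune:
    def test_celltype_single_class_rejected(self, small_sim):
        ds, _ = small_sim
        model, vocab = tiny_model(ds)
        idx = np.flatnonzero(ds.cell_type_labels == 0)
        with pytest.raises(ValueError, match="at least 2"):
            finetune_celltype(ds, model, vocab,
                              FinetuneConfig(epochs=1, max_peaks=64), train_idx=idx)

    def test_celltype_logs_freeze_then_unfreeze(self, small_sim):
        ds, _ = small_sim
        model, vocab = tiny_model(ds)
        log = finetune_celltype(
            ds, model, vocab,
            FinetuneConfig(epochs=3, batch_size=16, max_peaks=64,
                           freeze_encoder_epochs=2))
        frozen = [r["encoder_frozen"] for r in log.records]
        assert frozen == [True, True, False]

    def test_expression_mse_decreases(self, small_sim):
        ds, _ = small_sim
        model, vocab = tiny_model(ds)
        log = finetune_expression(
            ds, model, vocab,
            FinetuneConfig(epochs=4, batch_size=16, max_peaks=64, l_gene=16,
                           freeze_encoder_epochs=1))
        losses = log.losses()
        assert losses[-1] < losses[0]

    def test_constant_mean_predictor_mse_equals_bin_variance(self, small_sim):
        """The floor any useful expression model must beat."""
        ds, _ = small_sim
        bins = ds.expression_binned.astype(float)
        const = np.full_like(bins, bins.mean())
        rep = pg.regression_metrics(bins, const)
        assert np.isclose(rep["MSE"], bins.var(), rtol=1e-12)


class TestEmbeddings:
    def test_shape_and_duplicate_cells_identical(self, small_sim):
        ds, _ = small_sim
        model, vocab = tiny_model(ds)
        emb = extract_cell_embeddings(model, vocab, ds, max_peaks=64, seed=0)
        assert emb.shape == (ds.n_cells, 16)
        # a duplicated accessibility row embeds identically
        from dataclasses import replace
        import scipy.sparse as sp
        dup = sp.vstack([ds.accessibility, ds.accessibility[:1]]).tocsr()
        ds2 = replace(ds, accessibility=dup,
                      accessibility_raw=sp.vstack(
                          [ds.accessibility_raw, ds.accessibility_raw[:1]]).tocsr(),
                      expression_raw=sp.vstack(
                          [ds.expression_raw, ds.expression_raw[:1]]).tocsr(),
                      expression_binary=sp.vstack(
                          [ds.expression_binary, ds.expression_binary[:1]]).tocsr(),
                      expression_binned=np.vstack(
                          [ds.expression_binned, ds.expression_binned[:1]]),
                      cell_ids=ds.cell_ids + ["dup"],
                      batch_labels=np.r_[ds.batch_labels, ds.batch_labels[:1]],
                      cell_type_labels=np.r_[ds.cell_type_labels,
                                             ds.cell_type_labels[:1]])
        emb2 = extract_cell_embeddings(model, vocab, ds2, max_peaks=64, seed=0)
        assert np.allclose(emb2[0], emb2[-1])

    def test_permuted_pairings_keeps_accessibility(self, small_sim):
        ds, _ = small_sim
        perm = pg.permute_pairings(ds, seed=4)
        assert (perm.accessibility != ds.accessibility).nnz == 0
        assert perm.expression_binary.nnz == ds.expression_binary.nnz
        assert (perm.expression_binary != ds.expression_binary).nnz > 0
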