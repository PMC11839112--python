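"""scikit-learn style estimators wrapping the peak-set transformer.

* :class:`PeakToGeneEncoder` — ``fit`` runs peak-to-gene pre-training on
  a :class:`~peakgene.io.MultiomeDataset`; ``transform`` returns the
  batch-free cell embeddings ``z_c``.
* :class:`CellTypeAnnotator` — a classifier fine-tuning the cell-type
  head of a fitted encoder.
* :class:`BinnedExpressionRegressor` — fine-tunes the binned-expression
  head and predicts ordinal expression levels per gene.

All three follow the estimator contract (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``check_is_fitted``-style
errors) so they compose with sklearn model selection; ``X`` is a
``MultiomeDataset`` rather than an array, which sklearn tolerates as an
opaque object.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin
from sklearn.exceptions import NotFittedError

from .io import MultiomeDataset
from .model import ModelConfig, PeakSetModel
from .train import (
    FinetuneConfig,
    PretrainConfig,
    evaluate_binary_auroc,
    extract_cell_embeddings,
    finetune_celltype,
    finetune_expression,
    predict_binned_expression_matrix,
    predict_cell_types,
    pretrain,
)
from .vocab import PeakVocabulary

__all__ = ["PeakToGeneEncoder", "CellTypeAnnotator", "BinnedExpressionRegressor"]


class PeakToGeneEncoder(BaseEstimator, TransformerMixin):
    """Pre-trained peak-set transformer exposing cell embeddings.

    Parameters mirror the model and pre-training configs.  The
    documented full-scale settings are ``d_model=512, n_layers=6,
    n_heads=8, l_gene=8000, max_peaks=12000, epochs=140``; the defaults
    here are the desk-scale configuration the test-bed uses.
    """

    def __init__(self, d_model: int = 64, n_layers: int = 2, n_heads: int = 4,
                 ff_mult: int = 2, n_bins: int = 10, dropout: float = 0.0,
                 decoder_hidden: int | None = None,
                 use_chromosome_embedding: bool = True,
                 use_batch_embedding: bool = True,
                 l_gene: int = 256, epochs: int = 30, batch_size: int = 32,
                 grad_accum: int = 1, lr: float = 2e-3, weight_decay: float = 1e-4,
                 warmup_frac: float = 0.05, max_peaks: int = 512,
                 val_fraction: float = 0.15, random_state: int = 0):
        self.d_model = d_model
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.ff_mult = ff_mult
        self.n_bins = n_bins
        self.dropout = dropout
        self.decoder_hidden = decoder_hidden
        self.use_chromosome_embedding = use_chromosome_embedding
        self.use_batch_embedding = use_batch_embedding
        self.l_gene = l_gene
        self.epochs = epochs
        self.batch_size = batch_size
        self.grad_accum = grad_accum
        self.lr = lr
        self.weight_decay = weight_decay
        self.warmup_frac = warmup_frac
        self.max_peaks = max_peaks
        self.val_fraction = val_fraction
        self.random_state = random_state

    def fit(self, X: MultiomeDataset, y=None) -> "PeakToGeneEncoder":
        vocab = PeakVocabulary.from_annotation(X.peaks)
        config = ModelConfig(
            n_peaks=vocab.n_peaks, n_chroms=vocab.n_chroms,
            n_genes=X.n_genes, n_batches=max(1, X.n_batches),
            d_model=self.d_model, n_layers=self.n_layers, n_heads=self.n_heads,
            ff_mult=self.ff_mult, n_bins=self.n_bins, dropout=self.dropout,
            decoder_hidden=self.decoder_hidden,
            use_chromosome_embedding=self.use_chromosome_embedding,
            use_batch_embedding=self.use_batch_embedding,
            seed=self.random_state)
        model = PeakSetModel(config)
        pre = PretrainConfig(
            l_gene=self.l_gene, epochs=self.epochs, batch_size=self.batch_size,
            grad_accum=self.grad_accum, lr=self.lr,
            weight_decay=self.weight_decay, seed=self.random_state,
            warmup_frac=self.warmup_frac,
            max_peaks=self.max_peaks, val_fraction=self.val_fraction)
        self.log_ = pretrain(X, model, vocab, pre)
        self.model_ = model
        self.vocab_ = vocab
        aur = [r["val_auroc"] for r in self.log_.records if "val_auroc" in r]
        self.val_auroc_ = aur[-1] if aur else None
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("PeakToGeneEncoder is not fitted")

    def transform(self, X: MultiomeDataset) -> np.ndarray:
        """Batch-free cell embeddings z_c, one row per cell."""
        self._check_fitted()
        return extract_cell_embeddings(self.model_, self.vocab_, X,
                                       max_peaks=self.max_peaks,
                                       seed=self.random_state)

    def score(self, X: MultiomeDataset, y=None, cell_idx=None) -> float:
        """Pooled balanced binary-expression AUROC on the given cells."""
        self._check_fitted()
        cell_idx = np.arange(X.n_cells) if cell_idx is None else cell_idx
        return evaluate_binary_auroc(self.model_, self.vocab_, X, cell_idx,
                                     l_gene=self.l_gene, max_peaks=self.max_peaks,
                                     seed=self.random_state)


class CellTypeAnnotator(BaseEstimator, ClassifierMixin):
    """Cell-type classifier fine-tuned on a pre-trained encoder.

    The head consumes ``z_c`` only; the batch embedding is never used
    after pre-training.  The encoder is frozen for the first
    ``freeze_encoder_epochs`` epochs, then unfrozen.
    """

    def __init__(self, encoder: PeakToGeneEncoder | None = None,
                 epochs: int = 10, batch_size: int = 32, lr: float = 1e-3,
                 freeze_encoder_epochs: int = 2, unfreeze: bool = True,
                 random_state: int = 0):
        self.encoder = encoder
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.freeze_encoder_epochs = freeze_encoder_epochs
        self.unfreeze = unfreeze
        self.random_state = random_state

    def fit(self, X: MultiomeDataset, y=None, train_idx=None) -> "CellTypeAnnotator":
        if self.encoder is None or not hasattr(self.encoder, "model_"):
            raise NotFittedError("CellTypeAnnotator needs a fitted PeakToGeneEncoder")
        if y is not None:
            from dataclasses import replace
            y = np.asarray(y)
            names = [str(v) for v in np.unique(y)]
            codes = {v: i for i, v in enumerate(np.unique(y))}
            X = replace(X, cell_type_labels=np.array([codes[v] for v in y]),
                        cell_type_names=names)
        if X.cell_type_labels is None:
            raise ValueError("no labels: pass y or a dataset with cell_type_labels")
        config = FinetuneConfig(
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            seed=self.random_state, max_peaks=self.encoder.max_peaks,
            freeze_encoder_epochs=self.freeze_encoder_epochs,
            unfreeze=self.unfreeze)
        self.log_ = finetune_celltype(X, self.encoder.model_, self.encoder.vocab_,
                                      config, train_idx=train_idx)
        self.classes_ = np.arange(int(X.cell_type_labels.max()) + 1)
        self.class_names_ = X.cell_type_names
        return self

    def predict_proba(self, X: MultiomeDataset, cell_idx=None) -> np.ndarray:
        if not hasattr(self, "classes_"):
            raise NotFittedError("CellTypeAnnotator is not fitted")
        return predict_cell_types(self.encoder.model_, self.encoder.vocab_, X,
                                  cell_idx=cell_idx,
                                  max_peaks=self.encoder.max_peaks,
                                  seed=self.random_state)

    def predict(self, X: MultiomeDataset, cell_idx=None) -> np.ndarray:
        return self.predict_proba(X, cell_idx=cell_idx).argmax(axis=1)

    def score(self, X: MultiomeDataset, y=None, cell_idx=None) -> float:
        pred = self.predict(X, cell_idx=cell_idx)
        if y is None:
            idx = np.arange(X.n_cells) if cell_idx is None else np.asarray(cell_idx)
            y = X.cell_type_labels[idx]
        return float(np.mean(pred == np.asarray(y)))


class BinnedExpressionRegressor(BaseEstimator, RegressorMixin):
    """Ordinal expression predictor fine-tuned on a pre-trained encoder."""

    def __init__(self, encoder: PeakToGeneEncoder | None = None,
                 epochs: int = 10, batch_size: int = 32, lr: float = 1e-3,
                 l_gene: int = 256, freeze_encoder_epochs: int = 2,
                 unfreeze: bool = True, random_state: int = 0):
        self.encoder = encoder
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.l_gene = l_gene
        self.freeze_encoder_epochs = freeze_encoder_epochs
        self.unfreeze = unfreeze
        self.random_state = random_state

    def fit(self, X: MultiomeDataset, y=None, train_idx=None) -> "BinnedExpressionRegressor":
        if self.encoder is None or not hasattr(self.encoder, "model_"):
            raise NotFittedError("BinnedExpressionRegressor needs a fitted encoder")
        config = FinetuneConfig(
            epochs=self.epochs, batch_size=self.batch_size, lr=self.lr,
            seed=self.random_state, max_peaks=self.encoder.max_peaks,
            freeze_encoder_epochs=self.freeze_encoder_epochs,
            unfreeze=self.unfreeze, l_gene=self.l_gene)
        self.log_ = finetune_expression(X, self.encoder.model_,
                                        self.encoder.vocab_, config,
                                        train_idx=train_idx)
        self.n_bins_ = self.encoder.model_.config.n_bins
        return self

    def predict(self, X: MultiomeDataset, cell_idx=None, gene_ids=None) -> np.ndarray:
        if not hasattr(self, "n_bins_"):
            raise NotFittedError("BinnedExpressionRegressor is not fitted")
        return predict_binned_expression_matrix(
            self.encoder.model_, self.encoder.vocab_, X, cell_idx=cell_idx,
            gene_ids=gene_ids, max_peaks=self.encoder.max_peaks,
            seed=self.random_state)
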