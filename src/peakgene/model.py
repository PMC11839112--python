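"""The peak-set transformer: embeddings, encoder, and task decoders.

Architecture
------------
Each accessible peak token is embedded as the sum of a peak embedding and
the embedding of its chromosome (the chromosome term can be ablated).
A [CLS] token is prepended; after ``n_layers`` transformer blocks its
state ``z_c`` is the cell representation.  During pre-training ``z_c`` is
concatenated with a learned batch embedding ``z_b`` to give the corrected
representation ``z~_c``; batch information is used *only* there, so the
representation used for fine-tuning and evaluation stays batch-free.

Three decoder heads, each a two-layer GELU MLP of hidden width
``d_model``:

* ``d_pre``  — binary expression logit from ``[z~_c, e_gene]``
  (pre-training, one logit per sampled gene);
* ``d_cell`` — cell-type logits from ``z_c``;
* ``d_exp``  — scalar binned-expression value from ``[z_c, e_gene]``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Parameter, Tensor, concat, gather_rows
from .nn import Embedding, LayerNorm, Linear, Module, TransformerBlock
from .vocab import CellTokenSequence, PeakVocabulary, collate

__all__ = ["ModelConfig", "PeakSetModel"]


@dataclass
class ModelConfig:
    """Hyperparameters and vocabulary sizes for :class:`PeakSetModel`.

    The documented full-scale configuration is ``d_model=512``,
    ``n_layers=6``, ``n_heads=8``; desk-scale work uses 64/2/4.
    ``use_chromosome_embedding`` and ``use_batch_embedding`` are the two
    ablation switches; ``use_batch_in_expression_head`` controls whether
    the binned-expression head sees the batch half of ``z~_c`` (off by
    default: that head consumes the plain cell representation).
    """

    n_peaks: int
    n_chroms: int
    n_genes: int
    n_batches: int
    d_model: int = 512
    n_layers: int = 6
    n_heads: int = 8
    n_bins: int = 10
    ff_mult: int = 4
    dropout: float = 0.0
    decoder_hidden: int | None = None
    n_cell_types: int | None = None
    use_chromosome_embedding: bool = True
    use_batch_embedding: bool = True
    use_batch_in_expression_head: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        for name in ("n_peaks", "n_chroms", "n_genes", "n_batches", "d_model",
                     "n_heads", "n_bins"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")


class _MLPHead(Module):
    def __init__(self, n_in: int, hidden: int, n_out: int, rng):
        self.fc1 = Linear(n_in, hidden, rng)
        self.fc2 = Linear(hidden, n_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class PeakSetModel(Module):
    """Embedding tables, transformer encoder, and the three decoders."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d_model
        hidden = config.decoder_hidden or d
        # +2 peak rows for [CLS]/[PAD]; +1 chromosome row for the null id
        self.e_peak = Embedding(config.n_peaks + 2, d, rng)
        self.e_chr = Embedding(config.n_chroms + 1, d, rng)
        self.e_gene = Embedding(config.n_genes, d, rng)
        self.e_batch = Embedding(config.n_batches, d, rng)
        self.blocks = [TransformerBlock(d, config.n_heads, rng, config.ff_mult,
                                        config.dropout)
                       for _ in range(config.n_layers)]
        self.final_ln = LayerNorm(d)
        # decoder inputs: the (broadcast) cell representation, the gene
        # embedding, and their elementwise product z_c * e_gene — the
        # product term gives the head a first-order pathway to
        # gene-specific readout of the cell state
        self.d_pre = _MLPHead(4 * d, hidden, 1, rng)
        # per-gene output bias: calibrates gene base rates so the MLP
        # spends its capacity on the cell-dependent signal
        self.gene_bias = Parameter(np.zeros(config.n_genes))
        self.d_exp = _MLPHead((4 if config.use_batch_in_expression_head else 3) * d,
                              hidden, 1, rng)
        self.d_cell: _MLPHead | None = None
        if config.n_cell_types:
            self.init_cell_head(config.n_cell_types, rng)

    def init_cell_head(self, n_cell_types: int, rng=None) -> None:
        if n_cell_types < 2:
            raise ValueError("cell-type head needs at least 2 classes")
        rng = rng if rng is not None else np.random.default_rng(self.config.seed + 1)
        self.config.n_cell_types = n_cell_types
        self.d_cell = _MLPHead(self.config.d_model,
                               self.config.decoder_hidden or self.config.d_model,
                               n_cell_types, rng)

    # -- forward pieces -------------------------------------------------
    def embed_inputs(self, token_ids: np.ndarray, chrom_ids: np.ndarray) -> Tensor:
        """Input embedding: peak embedding plus (optionally) chromosome embedding."""
        z = self.e_peak(token_ids)
        if self.config.use_chromosome_embedding:
            z = z + self.e_chr(chrom_ids)
        return z

    def encode_cell(self, token_ids: np.ndarray, chrom_ids: np.ndarray,
                    mask: np.ndarray, train_rng=None) -> Tensor:
        """Cell representation z_c: the [CLS] state after all blocks.

        ``token_ids``/``chrom_ids``/``mask`` are (n_cells, length) with
        [CLS] at position 0.  With ``n_layers=0`` this degenerates to the
        [CLS] input embedding itself.  ``train_rng`` enables dropout
        (training only); evaluation passes are deterministic.
        """
        x = self.embed_inputs(token_ids, chrom_ids)
        if not self.blocks:
            return _slice_cls(x)
        for block in self.blocks:
            x = block(x, mask, train_rng=train_rng)
        x = self.final_ln(x)
        return _slice_cls(x)

    def fuse_batch(self, z_c: Tensor, batch_ids: np.ndarray) -> Tensor:
        """Corrected representation z~_c = [z_c, z_b] (2*d_model).

        With the batch-token ablation the second half is zeros, keeping
        the decoder input shape fixed.
        """
        batch_ids = np.asarray(batch_ids)
        if batch_ids.size and (batch_ids.min() < 0 or batch_ids.max() >= self.config.n_batches):
            raise IndexError("batch id out of range")
        if self.config.use_batch_embedding:
            zb = self.e_batch(batch_ids)
        else:
            zb = Tensor(np.zeros((z_c.shape[0], self.config.d_model)))
        return concat([z_c, zb], axis=-1)

    def _broadcast_over_genes(self, z: Tensor, gene_ids: np.ndarray) -> Tensor:
        """[z, e_gene[g], z_c * e_gene[g]] per requested gene.

        ``z`` is z_c or z~_c; its first d_model entries are always the
        cell representation, which supplies the product feature.  Genes
        are scored independently.
        """
        gene_ids = np.atleast_2d(np.asarray(gene_ids, dtype=np.int64))
        B, G = gene_ids.shape
        if z.shape[0] != B:
            if B == 1:
                gene_ids = np.broadcast_to(gene_ids, (z.shape[0], G)).copy()
                B = z.shape[0]
            else:
                raise ValueError("gene_ids rows must match number of cells")
        d = self.config.d_model
        zg = self.e_gene(gene_ids)                              # (B, G, d)
        ones = np.ones((B, G, 1))
        zb = z.reshape(B, 1, z.shape[-1]) * ones                # (B, G, k*d)
        zc_b = zb.narrow(0, d)                                  # (B, G, d)
        return concat([zb, zg, zc_b * zg], axis=-1)

    def predict_binary_expression_logits(self, z_tilde: Tensor,
                                         gene_ids: np.ndarray) -> Tensor:
        """Pre-training head: one binary-expression logit per (cell, gene)."""
        h = self._broadcast_over_genes(z_tilde, gene_ids)
        out = self.d_pre(h)
        logits = out.reshape(out.shape[0], out.shape[1])
        gene_ids = np.atleast_2d(np.asarray(gene_ids, dtype=np.int64))
        table = self.gene_bias.reshape(self.config.n_genes, 1)
        bias = gather_rows(table, gene_ids).reshape(*gene_ids.shape)
        return logits + bias

    def predict_binary_expression(self, z_tilde: Tensor, gene_ids) -> np.ndarray:
        gene_ids = np.asarray(gene_ids, dtype=np.int64)
        if gene_ids.size == 0:
            return np.zeros((z_tilde.shape[0], 0))
        return self.predict_binary_expression_logits(z_tilde, gene_ids).sigmoid().data

    def predict_cell_type_logits(self, z_c: Tensor) -> Tensor:
        if self.d_cell is None:
            raise RuntimeError("cell-type head not initialized; call init_cell_head")
        return self.d_cell(z_c)

    def predict_cell_type(self, z_c: Tensor) -> np.ndarray:
        """Softmax class scores over cell types (rows sum to 1)."""
        return self.predict_cell_type_logits(z_c).softmax(axis=-1).data

    def predict_binned_expression_raw(self, z: Tensor, gene_ids: np.ndarray) -> Tensor:
        """Unclamped scalar bin-space prediction per (cell, gene); used in training."""
        h = self._broadcast_over_genes(z, gene_ids)
        out = self.d_exp(h)
        return out.reshape(out.shape[0], out.shape[1])

    def predict_binned_expression(self, z: Tensor, gene_ids) -> np.ndarray:
        """Inference-time binned expression, clamped to [0, n_bins-1]."""
        gene_ids = np.asarray(gene_ids, dtype=np.int64)
        if gene_ids.size == 0:
            return np.zeros((z.shape[0], 0))
        raw = self.predict_binned_expression_raw(z, gene_ids).data
        return np.clip(raw, 0, self.config.n_bins - 1)

    # -- convenience ----------------------------------------------------
    def encode_sequences(self, sequences: list[CellTokenSequence],
                         vocab: PeakVocabulary) -> Tensor:
        tokens, chroms, mask = collate(sequences, vocab.pad_id, vocab.null_chrom_id)
        return self.encode_cell(tokens, chroms, mask)

    # -- persistence ----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        np.savez(path, **arrays)
        cfg_path = Path(str(path) + ".json")
        with open(cfg_path, "w") as fh:
            json.dump(asdict(self.config), fh)

    @classmethod
    def load(cls, path) -> "PeakSetModel":
        path = Path(path)
        with open(Path(str(path) + ".json")) as fh:
            config = ModelConfig(**json.load(fh))
        model = cls(config)
        with np.load(path) as npz:
            arrays = [npz[f"arr_{i}"] for i in range(len(npz.files))]
        model.load_state_arrays(arrays)
        return model


def _slice_cls(x: Tensor) -> Tensor:
    """Row 0 of the sequence axis: the [CLS] state per cell."""
    B, L, D = x.shape
    picker = np.zeros((1, L, 1))
    picker[0, 0, 0] = 1.0
    return (x * picker).sum(axis=1)
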