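"""Peak/chromosome vocabularies and set-of-peaks tokenization.

A cell is represented by the indices of its accessible (non-zero) peaks,
prefixed with a [CLS] token whose final-layer state becomes the cell
embedding.  Cells with more accessible peaks than ``max_peaks`` have
their excess peaks subsampled uniformly without replacement.  The [CLS]
token carries a dedicated null chromosome id with its own embedding row.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = ["PeakVocabulary", "CellTokenSequence", "tokenize_cell", "collate"]


@dataclass(frozen=True)
class CellTokenSequence:
    """Token ids ([CLS] first) and aligned chromosome ids for one cell."""

    token_ids: np.ndarray
    chrom_ids: np.ndarray

    def __len__(self) -> int:
        return len(self.token_ids)


class PeakVocabulary:
    """Bijective peak-id <-> index map plus chromosome indexing.

    Peak indices run ``0..n_peaks-1`` in input order; [CLS] and [PAD]
    take the two ids after the peak range.  Chromosome indices cover the
    chromosomes present (order of first appearance) plus a null id used
    by [CLS] and [PAD].
    """

    def __init__(self, peak_ids: list[str], peak_chroms: list[str]):
        if len(peak_ids) == 0:
            raise ValueError("peak list must be non-empty")
        if len(set(peak_ids)) != len(peak_ids):
            dup = pd.Series(peak_ids)
            raise ValueError(
                f"duplicate peak id {dup[dup.duplicated()].iloc[0]!r}")
        if len(peak_chroms) != len(peak_ids):
            raise ValueError("peak_ids and peak_chroms must align")
        self.peak_ids = list(peak_ids)
        self.peak_to_index = {p: i for i, p in enumerate(self.peak_ids)}
        self.chrom_names = list(dict.fromkeys(peak_chroms))
        chrom_idx = {c: i for i, c in enumerate(self.chrom_names)}
        self.peak_chrom_idx = np.array([chrom_idx[c] for c in peak_chroms], dtype=np.int64)

    @classmethod
    def from_annotation(cls, peaks: pd.DataFrame) -> "PeakVocabulary":
        return cls(peaks["peak_id"].tolist(), peaks["chrom"].tolist())

    # -- derived ids ----------------------------------------------------
    @property
    def n_peaks(self) -> int:
        return len(self.peak_ids)

    @property
    def n_chroms(self) -> int:
        return len(self.chrom_names)

    @property
    def null_chrom_id(self) -> int:
        return self.n_chroms

    @property
    def cls_id(self) -> int:
        return self.n_peaks

    @property
    def pad_id(self) -> int:
        return self.n_peaks + 1

    @property
    def n_token_ids(self) -> int:
        return self.n_peaks + 2

    # -- serialization --------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "peak_ids": self.peak_ids,
            "peak_chroms": [self.chrom_names[i] for i in self.peak_chrom_idx],
            "chrom_names": self.chrom_names,
            "cls_id": self.cls_id,
            "pad_id": self.pad_id,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PeakVocabulary":
        with open(path) as fh:
            payload = json.load(fh)
        vocab = cls(payload["peak_ids"], payload["peak_chroms"])
        if vocab.chrom_names != payload["chrom_names"]:
            raise ValueError("chromosome order in file does not match peak order")
        return vocab


def tokenize_cell(accessibility_row, vocab: PeakVocabulary, max_peaks: int,
                  rng: np.random.Generator | int | None = None) -> CellTokenSequence:
    """Turn one cell's binary accessibility row into a token sequence.

    If the cell has more than ``max_peaks`` accessible peaks, that many
    are drawn uniformly without replacement using ``rng``; otherwise all
    are kept in peak-index order.  An empty cell yields the CLS-only
    sequence (with a warning) so inference never aborts.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    if sp.issparse(accessibility_row):
        nz = accessibility_row.tocsr().indices.astype(np.int64)
        nz.sort()
        row_len = accessibility_row.shape[1]
    else:
        row = np.asarray(accessibility_row).ravel()
        nz = np.flatnonzero(row)
        row_len = row.size
    if row_len != vocab.n_peaks:
        raise ValueError(f"row length {row_len} != vocabulary size {vocab.n_peaks}")
    if nz.size == 0:
        logger.warning("cell has no accessible peaks; emitting CLS-only sequence")
    elif nz.size > max_peaks:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        nz = rng.choice(nz, size=max_peaks, replace=False)
    token_ids = np.concatenate([[vocab.cls_id], nz]).astype(np.int64)
    chrom_ids = np.concatenate(
        [[vocab.null_chrom_id], vocab.peak_chrom_idx[nz]]).astype(np.int64)
    return CellTokenSequence(token_ids=token_ids, chrom_ids=chrom_ids)


def collate(sequences: list[CellTokenSequence], pad_id: int,
            null_chrom_id: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pad sequences into rectangular id blocks plus a boolean mask.

    Returns ``(token_ids, chrom_ids, mask)`` each of shape
    (n_cells, max_len); the mask is True exactly on real tokens.
    """
    if not sequences:
        raise ValueError("cannot collate an empty list of sequences")
    lengths = np.array([len(s) for s in sequences])
    width = lengths.max()
    tokens = np.full((len(sequences), width), pad_id, dtype=np.int64)
    chroms = np.full((len(sequences), width), null_chrom_id, dtype=np.int64)
    mask = np.zeros((len(sequences), width), dtype=bool)
    for i, seq in enumerate(sequences):
        tokens[i, : len(seq)] = seq.token_ids
        chroms[i, : len(seq)] = seq.chrom_ids
        mask[i, : len(seq)] = True
    return tokens, chroms, mask
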