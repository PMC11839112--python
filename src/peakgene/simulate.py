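"""Synthetic paired multiome generator with known ground truth.

The generator emulates the structure the peak-set model assumes in real
10X Multiome data:

* **Cell-type peak programs** — each cell type activates one block of
  peaks: program peaks are accessible with probability ``p_on`` in cells
  of the matching type and ``p_off`` elsewhere (background peaks are
  ``p_off`` everywhere).
* **Batch effect** — batch ``b`` adds ``b * batch_shift`` to the logit
  of every peak's accessibility probability, a global technical shift
  orthogonal to cell type (types and batches are assigned
  independently).
* **Expression driven by accessible regulation** — every gene owns a
  fixed set of regulatory peaks drawn from its program; its latent
  activity in a cell is the fraction of those peaks accessible, and raw
  counts are Poisson with mean ``baseline_rate + expr_scale * activity``
  thinned by Bernoulli dropout.  The peak->gene map is returned as
  ground truth, which makes peak-to-gene alignment a checkable recovery
  problem rather than an article of faith.

Peaks and genes are tiled on two pseudo-chromosomes with non-overlapping
intervals so chromosome embeddings and interval-overlap logic are both
exercised.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import (
    MultiomeDataset,
    bin_expression,
    binarize_accessibility,
    binarize_expression,
    write_multiome,
)

__all__ = ["SimulationConfig", "SyntheticGroundTruth", "generate", "write_dataset"]

_CHROMS = ["chrS1", "chrS2"]


@dataclass
class SimulationConfig:
    """Defaults define the desk-scale study conditions used throughout.

    600 cells, 3 cell types (one 100-peak program each), 2 batches with a
    one-logit accessibility shift, 500 peaks, 200 genes (60 per program
    plus 20 background), ``p_on``/``p_off`` 0.6/0.02, Poisson expression
    with mean ``0.05 + 6 * activity`` and 5% dropout.
    """

    n_cells: int = 600
    n_peaks: int = 500
    n_genes: int = 200
    n_cell_types: int = 3
    n_batches: int = 2
    peaks_per_program: int = 100
    genes_per_program: int = 60
    regulatory_peaks_per_gene: int = 8
    p_on: float = 0.6
    p_off: float = 0.02
    batch_shift: float = 1.0
    expr_scale: float = 6.0
    baseline_rate: float = 0.05
    dropout: float = 0.05
    deterministic_expression: bool = False   # counts = round(mean): noise-free limit
    n_bins: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.p_off < self.p_on <= 1):
            raise ValueError("need 0 <= p_off < p_on <= 1")
        if self.n_cell_types * self.peaks_per_program > self.n_peaks:
            raise ValueError("programs larger than the peak pool")
        if self.n_cell_types * self.genes_per_program > self.n_genes:
            raise ValueError("gene programs larger than the gene pool")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        for name in ("n_cells", "n_peaks", "n_genes", "n_cell_types",
                     "n_batches", "regulatory_peaks_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticGroundTruth:
    """The generator's hidden state: the oracle for recovery tests."""

    peak_program: np.ndarray      # program id per peak, -1 = background
    gene_program: np.ndarray      # program id per gene, -1 = background
    regulatory_map: dict[int, list[int]]   # gene -> driving peaks
    cell_types: np.ndarray
    batches: np.ndarray
    config: SimulationConfig = field(repr=False, default=None)

    def to_json(self, path) -> None:
        payload = {
            "peak_program": self.peak_program.tolist(),
            "gene_program": self.gene_program.tolist(),
            "regulatory_map": {str(g): list(map(int, p))
                               for g, p in self.regulatory_map.items()},
            "cell_types": self.cell_types.tolist(),
            "batches": self.batches.tolist(),
            "config": asdict(self.config) if self.config else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = SimulationConfig(**payload["config"]) if payload.get("config") else None
        return cls(
            peak_program=np.asarray(payload["peak_program"]),
            gene_program=np.asarray(payload["gene_program"]),
            regulatory_map={int(g): list(p)
                            for g, p in payload["regulatory_map"].items()},
            cell_types=np.asarray(payload["cell_types"]),
            batches=np.asarray(payload["batches"]),
            config=cfg,
        )


def _tile_intervals(n: int, width: int, spacing: int) -> pd.DataFrame:
    chrom = [_CHROMS[i % len(_CHROMS)] for i in range(n)]
    start = [(i // len(_CHROMS)) * spacing for i in range(n)]
    return pd.DataFrame({"chrom": chrom, "start": start,
                         "end": [s + width for s in start]})


def generate(config: SimulationConfig) -> tuple[MultiomeDataset, SyntheticGroundTruth]:
    """Draw one paired dataset; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    T, P, G, N = (config.n_cell_types, config.n_peaks, config.n_genes,
                  config.n_cells)

    # program assignment in index order: programs first, background last
    peak_program = np.full(P, -1, dtype=np.int64)
    for t in range(T):
        peak_program[t * config.peaks_per_program:(t + 1) * config.peaks_per_program] = t
    gene_program = np.full(G, -1, dtype=np.int64)
    for t in range(T):
        gene_program[t * config.genes_per_program:(t + 1) * config.genes_per_program] = t

    background_peaks = np.flatnonzero(peak_program == -1)
    regulatory_map: dict[int, list[int]] = {}
    for g in range(G):
        pool = np.flatnonzero(peak_program == gene_program[g]) \
            if gene_program[g] >= 0 else background_peaks
        n_reg = min(config.regulatory_peaks_per_gene, len(pool))
        regulatory_map[g] = sorted(rng.choice(pool, size=n_reg, replace=False).tolist())

    # independent type and batch assignment (label-orthogonal batch effect)
    cell_types = rng.integers(0, T, size=N)
    batches = rng.integers(0, config.n_batches, size=N)

    with np.errstate(divide="ignore", over="ignore"):
        logit_on = np.log(config.p_on) - np.log1p(-config.p_on) \
            if config.p_on < 1 else np.inf
        logit_off = np.log(config.p_off) - np.log1p(-config.p_off) \
            if config.p_off > 0 else -np.inf
        base_logit = np.where(
            peak_program[None, :] == cell_types[:, None], logit_on, logit_off)
        logit = base_logit + (batches * config.batch_shift)[:, None]
        prob = 1.0 / (1.0 + np.exp(-logit))
    acc = (rng.random((N, P)) < prob).astype(np.int64)

    reg_idx = np.zeros((G, max(len(v) for v in regulatory_map.values())), dtype=np.int64)
    reg_len = np.array([len(regulatory_map[g]) for g in range(G)])
    for g in range(G):
        reg_idx[g, : reg_len[g]] = regulatory_map[g]
    # latent activity: fraction of a gene's regulatory peaks accessible
    activity = np.stack([acc[:, reg_idx[g, : reg_len[g]]].mean(axis=1)
                         for g in range(G)], axis=1)
    lam = config.baseline_rate + config.expr_scale * activity
    if config.deterministic_expression:
        expr = np.round(lam).astype(np.int64)
    else:
        expr = rng.poisson(lam).astype(np.int64)
    if config.dropout > 0:
        keep = rng.random((N, G)) >= config.dropout
        expr = expr * keep

    acc_sp = sp.csr_matrix(acc)
    expr_sp = sp.csr_matrix(expr)
    peaks = _tile_intervals(P, width=200, spacing=1000)
    peaks.insert(0, "peak_id", [f"{c}:{s}-{e}" for c, s, e in
                                zip(peaks["chrom"], peaks["start"], peaks["end"])])
    genes = _tile_intervals(G, width=400, spacing=2500)
    genes["start"] = genes["start"] + 300
    genes["end"] = genes["end"] + 300
    strand = ["+" if i % 2 == 0 else "-" for i in range(G)]
    genes = pd.DataFrame({
        "gene_id": [f"gene{g}" for g in range(G)],
        "chrom": genes["chrom"],
        "tss": [s if st == "+" else e - 1 for s, e, st in
                zip(genes["start"], genes["end"], strand)],
        "strand": strand,
        "body_start": genes["start"],
        "body_end": genes["end"],
    })

    type_names = [f"type{t}" for t in range(T)]
    batch_names = [f"batch{b}" for b in range(config.n_batches)]
    dataset = MultiomeDataset(
        accessibility_raw=acc_sp,
        accessibility=binarize_accessibility(acc_sp),
        expression_raw=expr_sp,
        expression_binary=binarize_expression(expr_sp),
        expression_binned=bin_expression(expr_sp, n_bins=config.n_bins),
        cell_ids=[f"cell{i}" for i in range(N)],
        batch_labels=batches.astype(np.int64),
        peaks=peaks,
        genes=genes,
        batch_names=batch_names,
        cell_type_labels=cell_types.astype(np.int64),
        cell_type_names=type_names,
        n_bins=config.n_bins,
    )
    dataset.validate()
    truth = SyntheticGroundTruth(
        peak_program=peak_program,
        gene_program=gene_program,
        regulatory_map=regulatory_map,
        cell_types=cell_types.astype(np.int64),
        batches=batches.astype(np.int64),
        config=config,
    )
    return dataset, truth


def write_dataset(dataset: MultiomeDataset, ground_truth: SyntheticGroundTruth,
                  out_dir, force: bool = False) -> dict[str, Path]:
    """Write the dataset in loadable form plus the ground truth as JSON."""
    paths = write_multiome(dataset, out_dir, force=force)
    gt_path = Path(out_dir) / "ground_truth.json"
    ground_truth.to_json(gt_path)
    paths["ground_truth"] = gt_path
    return paths
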