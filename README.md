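# peakgene

Set-based transformer cell embeddings from single-cell ATAC-seq peaks,
pre-trained across modalities by predicting paired gene expression.

## The problem

Single-cell ATAC-seq measures chromatin accessibility over hundreds of
thousands of peaks, but the signal is near-binary and extremely sparse:
what characterizes a cell is *which* peaks are open, not how open they
are. `peakgene` represents a cell `i` by its set of accessible peaks
`P_i⁺ = {p_k : A[i,k] = 1}` from the binarized peak-by-cell matrix
`A ∈ {0,1}^{N_C×N_P}`. Each peak token is embedded as the sum of a peak
embedding and its chromosome's embedding; a `[CLS]` token is prepended
and, after `N_L` transformer blocks (no positional encoding — the input
is a set), its final state `z_c ∈ R^{d_m}` is the cell representation.

Pre-training aligns the two modalities of 10X-Multiome-style paired
data: for each cell, a gene set with an equal number of expressed and
unexpressed genes is sampled, and a decoder predicts each gene's binary
expression `e^binary` from the batch-aware representation
`z̃_c = [z_c, z_b]` together with the gene's embedding, under
cross-entropy loss. The batch embedding `z_b` is used **only** during
pre-training, so `z_c` itself stays batch-free for downstream use.
Fine-tuning heads provide cell-type annotation (cross-entropy on `z_c`)
and ordinal expression prediction (MSE against `N_bin = 10` per-cell
expression levels).

The package is aimed at method developers and benchmarkers: it ships the
whole desk-scale pipeline — paired multiome I/O (Matrix Market + BED +
TSV), peak tokenization, the model and training loops (implemented on
numpy with an in-package reverse-mode autodiff core), scikit-learn style
estimators, a synthetic paired-multiome generator with a ground-truth
peak→gene regulatory map, the standard single-cell integration metric
suite (ISO, NMI, cASW, cLISI, bASW, GC), classification/regression
metrics, a PCA baseline, and the Signac-style Gene Activity comparator.

## Worked example

```python
import numpy as np
import peakgene as pg

# a paired multiome with known regulation: 600 cells, 3 cell types,
# 2 batches, 500 peaks (3 x 100-peak programs), 200 genes
dataset, truth = pg.generate(pg.SimulationConfig(seed=1))

encoder = pg.PeakToGeneEncoder(epochs=30, random_state=0)   # d_m=64, 2 layers
encoder.fit(dataset)
print(f"held-out binary-expression AUROC: {encoder.val_auroc_:.3f}")

control = pg.PeakToGeneEncoder(epochs=30, random_state=0)
control.fit(pg.permute_pairings(dataset, seed=2))           # null pairing
print(f"permuted-control AUROC:          {control.val_auroc_:.3f}")

embeddings = encoder.transform(dataset)                     # 600 x 64, batch-free
report = pg.batch_integration_metrics(
    embeddings, dataset.cell_type_labels, dataset.batch_labels)
print(f"bASW {report['bASW']:.3f}  GC {report['GC']:.3f}")
```

Output:

```
held-out binary-expression AUROC: 0.849
permuted-control AUROC:          0.541
bASW 0.830  GC 1.000
```

The AUROC is macro-averaged per gene over held-out cells: ~0.85 means
the model has learned *which cells* express each gene from accessibility
alone (the generator's Bayes-optimal score under the true regulatory map
is 0.92), while the permuted control — identical training on decoupled
cell–expression pairings — sits at chance, showing the signal is genuine
cross-modality alignment rather than memorized gene statistics.

A `peakgene` command-line interface exposes the same pipeline as
subcommands (`simulate`, `pretrain`, `finetune-celltype`,
`finetune-expression`, `embed`, `evaluate`), each taking
`--config <yaml> --seed <int> --out-dir <dir>`.

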