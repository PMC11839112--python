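# Methods

## Model

A cell is its set of accessible peaks. The binarized accessibility
matrix `A` (1 wherever the raw fragment count is positive) defines the
non-zero peak set `P_i⁺` of cell `i`; each member peak becomes one input
token. The input embedding of a token is the sum of its peak embedding
(`E_peak`, one row per peak plus reserved `[CLS]`/`[PAD]` rows) and the
embedding of its chromosome (`E_chr`, one row per chromosome plus a null
row used by `[CLS]`/`[PAD]`). A `[CLS]` token is prepended, the sequence
passes through `N_L` pre-LayerNorm transformer blocks with standard
scaled-dot-product attention and a key-padding mask, and the final-layer
`[CLS]` state `z_c` is the cell representation. There are **no
positional embeddings**: the encoder is permutation-invariant over peak
tokens by construction, and the test suite asserts this to relative
tolerance 1e-5 rather than trusting it. Cells with more accessible
peaks than the cap `L_peak` have their peaks subsampled uniformly
without replacement (redrawn every epoch by default); cells with none
yield a `[CLS]`-only sequence with a warning instead of an error.

During pre-training, `z_c` is concatenated with a learned batch
embedding `z_b` to give `z̃_c`; batch information is used only there, so
embeddings used downstream are batch-free. For each cell a gene set
with equal numbers of expressed and unexpressed genes is drawn
(`k = min(L_gene/2, n_expressed, n_unexpressed)` per class, uniformly
without replacement), and the binary head scores each gene
independently from `[z̃_c, e_g, z_c ⊙ e_g]` through a two-layer GELU MLP
plus a per-gene output bias, under mean binary cross-entropy (mean over
a cell's genes, then over cells — this reduction, not the global mean,
defines the gradients). The elementwise-product input and the per-gene
bias are deliberate decoder choices: with concatenation alone the
decoder must synthesize the cell-by-gene interaction from additive
features, and at desk scale optimization reproducibly stalls in a
"cell-type-only" solution; the product term provides the interaction
directly and the bias absorbs gene base rates.

Two fine-tuning heads share the encoder. Cell-type annotation applies a
two-layer MLP to `z_c` with cross-entropy; binned expression prediction
scores `[z_c, e_g, z_c ⊙ e_g]` with MSE against integer expression
levels and is clamped to `[0, N_bin−1]` at inference. Whether the
expression head additionally sees `z_b` is a switch
(`use_batch_in_expression_head`), off by default. Fine-tuning freezes
the encoder for the first epochs (default 1–2), then unfreezes;
both all-frozen and all-unfrozen variants are configurable.

Held-out binary-expression AUROC is **macro-averaged per gene**: every
gene is scored on all held-out cells and genes with both classes present
contribute one AUROC each. This makes the score measure cross-modality
alignment — does the model know *which cells* express a gene — and makes
a gene-popularity-only model score exactly 0.5, so the permuted-pairing
control is a true null. A pooled variant (one ROC over all cell–gene
pairs from balanced per-cell samples) is available but conflates
alignment with base-rate learning.

## Expression binarization and binning

Binary expression is the indicator of a positive raw count. Ordinal
levels are per-cell: zeros pin to bin 0; non-zero values are
library-size normalized to 10,000, log1p-transformed, and assigned to
bins `1..N_bin−1` by within-cell quantiles of the non-zero values
(ties share a bin). Binning is monotone in the raw value and invariant
to scaling a cell's row by any positive constant.

## Architecture and training defaults

Full-scale documented configuration: `d_m = 512`, `N_L = 6`, 8 heads,
`L_peak = 12,000`, `L_gene = 8,000`, 140 epochs, batch size 8 with 20
gradient-accumulation steps. Desk-scale defaults (what the estimators,
tests, and acceptance script use): `d_m = 64`, `N_L = 2`, 4 heads,
feed-forward width `2·d_m`, decoder hidden width `d_m`, `L_peak = 512`,
`L_gene = 256`, 30 epochs, batch size 32, no accumulation. The
optimizer is Adam (`lr = 2e-3` desk scale, decoupled weight decay
`1e-4`) under a linear-warmup (5%) then cosine schedule; dropout and
Polyak averaging are available but off by default, as neither improved
held-out AUROC at this scale. The entire network and its training run
on numpy via an in-package reverse-mode autodiff engine
(`peakgene.autograd`), gradient-checked against central finite
differences in the test suite; all arithmetic is float64 and seeded runs
reproduce loss curves bit-for-bit.

## Synthetic paired multiome

The generator emulates the structure this model assumes in real 10X
Multiome data, with every hidden variable returned as ground truth:

* **Accessibility** — each cell type activates one block of program
  peaks (`p_on = 0.6` within the matching type, `p_off = 0.02`
  elsewhere and for background peaks). Batch `b` adds `b · 1.0` to
  every accessibility logit: a purely technical global shift,
  assigned independently of cell type.
* **Expression** — each gene owns 8 regulatory peaks drawn from its
  program; its activity in a cell is the fraction of those peaks open,
  and counts are Poisson with mean `0.05 + 6 · activity`, thinned by 5%
  dropout. 180 of 200 genes belong to the three programs; 20 are
  background genes regulated by background peaks.
* **Geometry** — peaks and genes are tiled on two pseudo-chromosomes as
  non-overlapping intervals, so chromosome embeddings and the
  interval-overlap logic of Gene Activity are genuinely exercised.

Study size throughout: 600 cells, 3 types, 2 batches, 500 peaks, 200
genes (~84 accessible peaks per cell). These sizes keep one full
pre-training run under ~3 minutes on one CPU core; the acceptance
script's ablation arm uses 10-epoch runs for the same reason.

What the generator does **not** emulate: genome-scale peak counts
(10⁵–10⁶), overlapping or hierarchical cell-type programs (available
via config but not default), distance-dependent peak–gene regulation
(regulatory peaks are program-matched, not proximity-matched, so Gene
Activity is a genuine baseline rather than an oracle), read-depth
variation per cell, and doublets. Passing tests therefore demonstrate
method correctness and recoverability of planted structure — not
performance on real tissue atlases.

## Evaluation metrics

Biological conservation: NMI between cell types and a Leiden clustering
of the embedding's kNN graph with the resolution swept (0.1–2.0) and
NMI maximized, with a fixed-k k-means fallback for tiny inputs; cASW =
(mean silhouette over cell types + 1)/2; cLISI is the inverse Simpson
index of cell-type composition over each cell's k nearest neighbors,
scaled so 1 means perfect separation; ISO takes the label(s) present in
the fewest batches and reports the best label-vs-rest silhouette
rescaled to [0,1]. Batch integration: bASW averages
`mean(1 − |silhouette w.r.t. batch|)` within each cell type (a type
confined to one batch contributes 1); GC averages, over types, the
largest-connected-component fraction of the type's induced kNN
subgraph. The kNN graph is Euclidean, `k = 15` by default, symmetrized
by union, self excluded. All of these are checked against brute-force
loop implementations to 1e-9 on small instances. Classification
metrics are ACC, macro/micro F1, and one-vs-rest macro-averaged
ROC-AUC (classes absent from the truth are excluded with a warning);
regression metrics are MSE, Spearman, and Pearson, flattened over all
cell–gene pairs, with zero-variance correlations reported as NaN rather
than 0.

Gene Activity sums peak counts over the gene body extended 2,000 bp
upstream of the TSS (strand-aware; 0-based half-open intervals; overlap
= any shared base). The PCA baseline is centered full-SVD PCA of the
binary accessibility matrix.

## Numerical and design notes

* Accessibility binarization thresholds at > 0 (a count of exactly 1
  must stay 1 in a binary matrix).
* Batch names map to dense codes in file order; round-trips preserve
  identity at the name level, not necessarily the integer coding.
* Gene TSS convention: `body_start` on +, `body_end − 1` on −.
* Ties in tokenization order: peaks keep index order when all fit, and
  sampled order otherwise — immaterial because the encoder is
  permutation-invariant.
* `n_layers = 0` degenerates to the `[CLS]` input embedding (no final
  LayerNorm), which the tests use as an identity limit.
* Empty gene lists, empty cells, single-class fine-tuning labels, and
  unknown batch/token/chromosome ids all have defined behavior
  (empty outputs, `[CLS]`-only sequences, and explicit errors,
  respectively).

## Known limitations

The desk-scale study is finite-sample-limited: with 510 training cells,
even a per-gene logistic model on the *uncompressed* 500-dim
accessibility reaches only ~0.84 held-out per-gene AUROC, and the
transformer's ~0.85 should be read against that, not against the
Bayes-optimal 0.92 available to an oracle that knows the regulatory
map. Background genes (regulated by rarely-open background peaks) are
the hardest class, since their signal must survive compression into a
64-dim cell state. The attention implementation is a plain O(L²)
kernel; at the full-scale `L_peak = 12,000` a fused attention kernel
and GPU execution would be required in practice.
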