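# Methods

This note documents the models, protocols and numerical choices behind
`scbench`, in the spirit of the methods documentation of mature scientific
packages: what is computed, under which assumptions, and where the design was
genuinely open.

## Data model and preprocessing

The central container is `SCDataset`: a cells × genes non-negative matrix
`X`, named layers of identical shape (`"raw"` always holds the original
integer counts; `"normalized"` the library-size-normalized values), per-cell
and per-gene annotation tables, and an append-only log of `(transform,
params)` records.  Cells are rows everywhere; the 10x-style Matrix Market
triplet on disk is genes × cells and is transposed at the IO boundary, where
1-based Matrix Market indices are also converted to 0-based.

Transforms are pure functions carrying a flat, JSON-serializable parameter
map, so a `Pipeline` round-trips through JSON bit-exactly.  Defaults:

| transform | default | rationale |
|---|---|---|
| `filter_features` | genes expressed in ≥ 3 cells | "rarely expressed" is not standardized; 3 cells is a common, documented floor |
| `normalize_total` | target sum 10⁴ per cell | the usual CP10K convention |
| `log1p` | — | variance stabilization for count data |
| `select_top_genes` | k = 3000, ranked by **total counts** | the selection targets highly *expressed* (not highly variable) genes; a dispersion ranking is deliberately not the default |
| `zscore_scale` | population variance, clip at ±10 | clipping guards the autoencoders against extreme standardized outliers |

PCA uses full SVD with centered data and a deterministic sign convention
(the largest-magnitude loading of each component is made positive), which
makes embeddings identical across runs regardless of the seed argument.

## Graph construction

The weighted bipartite cell–gene graph has an edge between cell *c* and gene
*g* iff the raw count X[c, g] > 0, with weight

  w(c, g) = X[c, g] / Σ_k X[c, k],

i.e. each cell's incident weights sum to exactly 1; no edge ever joins two
cells or two genes.  The normalization is per cell, consistent with the
library-size normalization used elsewhere in the package.  Adjacency
normalization offers the symmetric (D^-1/2 A D^-1/2) and row-stochastic
(D^-1 A) operators, with optional unit self-loops added before degrees are
computed; `propagate` is then a single linear message-passing step.  The kNN
cell–cell graph is the mutualized union of directed k-nearest
neighbourhoods with unit weights and index-order tie-breaking, so duplicated
points yield a reproducible graph.

## Clustering

### ZINB autoencoder with DEC self-training

The count noise model is the zero-inflated negative binomial: per-entry mean
μ > 0, per-gene dispersion θ > 0, per-entry dropout probability π ∈ [0, 1],
with NB(x; μ, θ) = Γ(x+θ)/(Γ(θ) x!) · (θ/(θ+μ))^θ (μ/(θ+μ))^x and a point
mass mixed at zero.  The autoencoder (encoder widths 256–64, latent d = 32;
decoder mirrored) reads standardized log-normalized expression and emits
three heads: exp-linear μ scaled by per-cell size factors (raw totals over
their median), softplus θ (one per gene, clamped to [10⁻⁴, 10⁴]), sigmoid π.

Training proceeds in three stages:

1. **Pretraining** — full-batch Adam (lr 10⁻³, 200 epochs) on the mean ZINB
   negative log-likelihood of the raw counts.
2. **Centroid initialization** — Lloyd's algorithm (20 restarts, best
   inertia, seeded) on the latent embedding.
3. **Self-training** — Student-t soft assignments
   q_ij ∝ (1 + ‖z_i − μ_j‖²/α)^−(α+1)/2 (α = 1) are sharpened into
   p_ij ∝ q_ij²/f_j (f_j the soft cluster frequency), and the joint loss
   NLL + γ·KL(P‖Q) (γ = 1) is minimized, refreshing P every 10 epochs and
   stopping once fewer than 0.1 % of hard labels change at a refresh (or at
   100 epochs).

The constrained variant adds a pairwise penalty
−Σ_ML log(q_a·q_b) − Σ_CL log(1 − q_a·q_b) over must-link / cannot-link
pairs.  The public `pairwise_constraint_loss` returns this sum; the trainer
weights it by λ = 1 after dividing by the number of pairs, so the term's
scale does not grow with the constraint budget.

All gradients flow through a small reverse-mode autodiff engine written for
this package (float64, CPU, deterministic), which also powers every other
neural model here; `gammaln` gradients use the digamma function.

### Graph autoencoder clustering

On the symmetric-normalized bipartite graph Â (with self-loops), node
features are the scaled expression rows for cells and one-hot rows for
genes; the encoder is Z = Â·ReLU(Â H₀ W₁) W₂ (hidden 256, latent 32).  The
decoder regresses the cell–gene edge weights (rescaled by their mean so
targets are O(1)) from z_c·z_g, with squared error over observed edges plus
an equally sized per-epoch resample of non-edges.  Training uses Adam at
lr 10⁻³ for 100 epochs — deliberately gentle, since the propagation
initialization already separates cell types and aggressive optimization of
the edge objective can erode that structure.  Final labels come from Lloyd's
algorithm on the cell embeddings.

## Cell-type annotation

Three classifiers share the fit–predict–score contract and a closed label
vocabulary (accuracy is closed-set; cells whose true label was never seen in
training are excluded from scoring with a warning):

* **logistic regression** — softmax-linear model, minibatch (64) Adam-SGD,
  L2 penalty 10⁻⁴, 100 epochs over standardized features;
* **MLP** — the same trainer with hidden layers 100–50–25 (ReLU); an empty
  hidden tuple reduces exactly to the logistic model;
* **graph classifier** — transductive: one cell–gene graph over train and
  test cells together, embeddings E = Â·ReLU(Â H₀ W₁), linear softmax head
  trained by cross-entropy on the labeled cells only.  The head is
  zero-initialized, so the initial training loss is log K independent of
  which unlabeled cells are present in the graph.

Inverse-frequency class weights are available but off by default.

## Imputation benchmark

Dropouts are simulated by choosing ⌊fraction · nnz⌋ (default 10 %) distinct
nonzero raw entries uniformly at random, zeroing them in the working matrix
and storing the originals in a held-out map that no training path reads
(enforced by a test that permutes the held-out values and requires an
identical fit).

**Evaluation scale.**  Masked-entry MSE is computed on library-size
normalized (10⁴), log1p-transformed values.  The truth matrix restores the
held-out counts but reuses the *working* matrix's per-cell normalization
factors, so truth and working values agree exactly at every unmasked entry
and the score isolates the masked positions.

* **Block MLP imputer** — genes are partitioned into deterministic blocks
  (default 256, hence a single block on the bundled fixtures); each block's
  predictor set is the union over its targets of the 5 most |Pearson|-
  correlated other genes, with correlations computed on pairwise-unmasked
  entries only (masked entries are treated as missing, not zero, to avoid
  leaking the mask).  One single-hidden-layer net (width 64, ReLU output
  clamp) per block is trained with value-weighted squared error (weight =
  target value, so masked and true zeros carry no weight), Adam lr 5·10⁻³,
  300 epochs.
* **Graph autoencoder imputer** — embeddings from two propagation layers
  over the masked matrix's cell–gene graph (hidden 128, latent 64);
  reconstruction softplus(z_c·z_g + b_c + b_g), where the cell and gene
  biases absorb library-size and mean-expression effects and the gene bias
  starts at the observed per-gene mean.  Training uses Adam at lr 10⁻² for
  300 epochs — gentler rates proved materially more stable across seeds
  than larger ones.  The loss is the mean squared error
  over the union of all observed unmasked nonzero entries and an
  equal-count per-epoch resample of observed zeros; averaging over the
  union (rather than averaging the two groups separately) keeps the zero
  term from dominating on dense matrices.
* **Gene-mean floor** — every entry of gene g replaced by the mean of g's
  observed unmasked values (0 if none).  Both imputers must beat this floor
  in masked MSE; this is the package's acceptance bar for the task.

## Spatial deconvolution

The signature matrix S (genes × types) holds per-type means of
library-size-normalized reference expression, restricted to the union of
each type's top-`n_markers` genes by fold change (type mean over the mean
of the other types, ε-stabilized, gene-id tie-break).

* **NNLS** — per spot, min_{β≥0} ‖y − Sβ‖² by the Lawson–Hanson active-set
  method, then β is normalized onto the simplex (an all-zero solution
  yields a uniform row with a warning).  With `log_weighting`, three IRLS
  rounds with per-gene weights 1/(ŷ_g + 1)² approximate a log-normal
  multiplicative error model; the +1 floor keeps zero-count genes from
  dominating.
* **Seeded NMF** — the reference (genes × cells, normalized, restricted to
  signature genes) is factorized V ≈ WH by Frobenius multiplicative updates
  (200 iterations), W seeded from the signature columns (ε-floored) and H
  from NNLS of the reference onto W; the objective is non-increasing.
  Because multiplicative updates let topics drift from their seeds, spot
  proportions are *not* read off W directly: each reference cell's final
  topic loadings are simplex-normalized and averaged per type into topic
  profiles Q, and a spot's proportions are NNLS(Q, simplex(NNLS(W, y))).
  This two-stage read-out restores the topic-to-type identification and is
  the package's analogue of per-type topic profiles in seeded-NMF
  deconvolution methods.

Proportions are always reported on the simplex; absolute abundances are not.

## Synthetic data

`simulate_counts` draws per-gene baseline means log-normal(μ=1, σ=1),
up-/down-regulates a disjoint `de_fraction` of genes per type by factor
exp(±lfc), scales each type profile to the target depth (2000 counts/cell),
draws negative-binomial counts (dispersion θ = 2) and applies uniform
dropout.  Uniform (rather than mean-dependent) dropout is the default for
analytic transparency.  `simulate_mixtures` draws per-spot Dirichlet
proportions and Poisson counts around the proportion-weighted type mean
profiles at depth 10⁴.

Named fixtures (all deterministic, seed embedded):

* `synth_blobs4` — 400 cells × 200 genes, 4 balanced types, lfc 2,
  dropout 0.1: the easy recovery benchmark.
* `synth_hard4` — same sizes, lfc 1, dropout 0.3: deliberately hard; used
  for the constraint non-inferiority check, where absolute ARI is low by
  construction.
* `synth_mix4` / `synth_mix4_ref` — 100 spots, Dirichlet(1,1,1,1),
  depth 10⁴, over a dropout-free 4-type reference.

What the generator does **not** emulate: batch effects, mean-dependent
dropout, gene–gene co-regulation beyond type structure, spatial
autocorrelation, ambient RNA, doublets.  Passing recovery tests on these
fixtures therefore demonstrates correctness of the algorithms under their
own noise assumptions, not performance on real tissue data.

## Benchmark harness

A `RunConfig` (task, model, dataset, hyperparameters, seeds, device)
serializes to exactly one canonical command line (sorted flags, JSON-encoded
parameter values) and parses back to an equal config; unknown flags are
rejected.  `run_benchmark` executes load → preprocess → fit → predict →
score per seed and reports per-seed metrics with mean/sd; per-seed failures
are recorded and the summary covers the successes, with a warning.  The
default seed protocol is the fixed list 0–19; grid search enumerates the
Cartesian product of a finite space in sorted-key order and ranks by the
task's primary metric (ARI / accuracy maximized, MSE minimized), ties
resolved by enumeration order.

## Numerical choices

* ε = 10⁻¹⁰ inside logs and denominators throughout; softplus/exp inputs
  clamped to avoid overflow.
* ARI is computed from the contingency table with the convention that a
  vanishing chance denominator (both partitions all-singletons or both
  single-cluster — necessarily identical partitions) scores 1.0; NMI uses
  natural logs, arithmetic-mean normalization by default (geometric
  optional) and scores 0 whenever either labeling has zero entropy.
* Gene selection, marker ranking and kNN construction all break ties by
  identifier / index order, never by hash order.
* All randomness flows through `numpy.random.default_rng(seed)`; model
  configs carry their own seed and training is full-batch or seeded-
  minibatch, so repeated fits are bit-identical.

## Problem sizes

The bundled fixtures (400 × 200; 100 spots) and the smaller unit-test
datasets (~120 × 80) were chosen so every model trains in seconds on one
CPU while keeping the per-type differential signal realistic for
well-separated benchmark data.  The deep models' reported numbers average 3
seeds; the constraint non-inferiority check uses 5 in the test suite.

## Known limitations

* The graph-autoencoder imputer primarily learns calibrated per-gene and
  per-cell effects on dense fixtures; its advantage over the gene-mean
  floor comes from calibration plus modest structure, and it can trail the
  block MLP.
* The transductive graph annotator has no inductive mode: predictions exist
  only for cells present in the training graph.
* Automatic selection of the number of clusters K is out of scope; K is an
  input.
* The scorers assume a shared gene vocabulary after preprocessing;
  cross-species or cross-panel mapping is not attempted.
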