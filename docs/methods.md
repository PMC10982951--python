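# Methods

## Hierarchy layering and mask compilation

The pathway scaffold is a child→parent relation table (Reactome dialect)
plus GMT gene sets. We orient layers by distance from the gene-carrying
leaves: layer 1 holds the most specific pathways (the ones with gene
sets), layer 5 the root-adjacent entities, matching the gene→phenotype
direction of information flow. A node's layer is its *minimum* leaf
distance; edges that then skip layers are removed, and a fixed-point loop
drops (a) non-top nodes without successors, (b) non-leaf nodes without
predecessors, and (c) layer-1 candidates without gene sets, re-deriving
layers until stable. An empty result raises ("no 5-layer backbone").
Genes form an explicit stratum between the omics features and layer 1,
with their own feature→gene and gene→pathway masks; gene symbols are
uppercased, pathway identifiers taken verbatim. Five pathway layers are
the default; every routine works for any depth ≥ 1 (tests exercise depths
3 and 5).

The masks are dense 0/1 matrices (`pathway_masks[i][j,k] = 1` iff edge
(node j, layer i) → (node k, layer i+1) exists). Mask columns are never
all-zero — a neuron with no inputs would be constant; `build_masks`
re-prunes the hierarchy if restricting gene sets to measured genes empties
a layer-1 pathway.

## The masked network

Masked layers compute `tanh((M ∘ W)ᵀ x + b)`; the elementwise product is
applied at *every* forward call, so dead positions cannot leak signal
regardless of what the optimizer writes there (gradients are masked too,
and a test randomizes dead positions after training and asserts identical
outputs). The head is the smallest genuine MLP: one hidden tanh layer of
width 8, then a single sigmoid output; the pre-sigmoid logit is the
attribution target. Predictions are clipped to [1e−7, 1−1e−7] inside the
loss to keep the log finite.

Training is full-batch Adam (lr 1e−2, 100 epochs) with early stopping on
a stratified 10% validation split (patience 10, best parameters
restored). The learning rate was set so the optimizer actually reaches
the low-loss regime within the epoch budget at the scales this package
targets (at 1e−3 the loss plateaus near its initial value after 100
epochs). Initialization is Glorot-uniform restricted to masked positions,
seed-controlled; the networks and gradients are implemented directly in
numpy (the models are tiny — a few thousand parameters — so a
deep-learning framework would add nothing), with a finite-difference
gradient check in the test suite.

Class weights default to inverse-frequency `w_c = N/(2 N_c)`, so a
134/371 imbalance yields w₁/w₀ = 371/134 and balanced data yields (1, 1).

## Preprocessing

Noise filtering drops features with variance below `min_variance`
(constants always drop) or missing fraction above `max_missing_frac`
(default 0.2; the cut-offs are conventions of this package), then imputes
remaining missing values to 0 — consistent with the all-zero attribution
reference meaning "no aberration". CNV is split as amp = max(v, 0),
del = max(−v, 0); the deletion block is a magnitude so the non-negative
chi-square score applies uniformly. Per block, features are ranked by the
standard feature-selection chi-square (observed class-wise sums vs.
expectation under class priors, df = 1; scikit-learn's `chi2`), ascending
P, ties by descending statistic then lexicographic id; the top k
(default 3000) are kept. Selection runs *inside* each CV training fold by
default — selecting on the full data leaks labels into evaluation folds —
with `select_in_fold=False` available to reproduce selection-first
protocols.

## Latent link augmentation

The GCN encoder is two layers (ReLU hidden, linear output, widths 64/32)
over the symmetrized hierarchy adjacency with self-loops and symmetric
normalization. Node features are binary gene-membership vectors; non-leaf
nodes take the union of their descendants' sets. The training objective —
not fixed by the decoder alone — is graph-autoencoder edge
reconstruction: binary cross-entropy on sigmoid(ĥᵤ·ĥᵥ) over known edges
vs. uniformly sampled non-edges (1:1 by default), Adam lr 1e−2, 200
epochs, seeded. Candidate links are restricted to adjacent-layer pairs
(directedness is restored from the layer indices); a link is added iff
its score is strictly above the threshold (default 0.9), and the original
mask pattern is asserted unchanged on every call. On the small synthetic
hierarchies the conservative 0.9 threshold typically admits zero to a few
links; the examples show the threshold sweep.

## Attribution

Contributions use the Rescale rule: linear segments carry multiplier
W_eff, each nonlinearity the elementwise Δout/Δin (fallback to the
analytic derivative when |Δin| < 1e−7). Chaining multipliers from the
logit conserves Σ C = t − t⁰ at every stratum exactly in exact
arithmetic; tests assert 1e−5 relative and observe ~1e−14. The literal
"gradient × Δt" formula is available as a diagnostic mode but is not
conservative and is excluded from the scientific path. Global scores sum
signed contributions over all samples by default (per-class sums and
mean-|C| are emitted as diagnostics); ranking is by |SC| with
lexicographic tie-breaks. Exports (per-layer TSV, JSON graph) write
floats with full round-trip precision so re-reading is bit-exact.

## Synthetic study conditions

The generator emulates a recurrence cohort: 505 samples with exactly 134
positives (26.5%), 64 genes in 8 leaf pathways under a (8, 5, 3, 2, 1)
hierarchy, SNV ~ Bernoulli(0.05), CNV ~ round(N(0, 0.6)) clipped to
[−2, 2]. Eight informative genes (one per leaf) carry the planted signal:
mutation rate ×(1 + effect) and CNV mean +effect in positives. The
default effect size is 1.0 — chosen so each informative gene is
individually informative (univariate AUC ≈ 0.83) without saturating the
clipped copy-number scale; a +2 shift would make every informative gene
individually near-perfect and the planted set redundant, which neither
resembles real effect sizes nor exercises multivariate recovery.
Generation is a pure function of the spec (same spec ⇒ byte-identical
files).

What the generator does **not** emulate: linkage between copy-number
segments, mutational signatures, inter-gene correlation, covariates, or
missingness structure. Passing tests therefore demonstrate algorithmic
correctness and recoverability under clean planted signals, not clinical
performance on real cohorts.

## Problem sizes and determinism

Cross-validation defaults to 5 folds × 5 repeats (25 fits); the reference
studies in the tests and acceptance script use 5 × 2 and a 10-seed sweep,
sizes at which the full pipeline runs in seconds per study. The repeat
index perturbs the fold-shuffling seed deterministically and each fold's
training seed is derived from (master seed, repeat, fold), so a master
seed fixes every output bit-exactly — CV CSVs and importance exports are
asserted byte-identical across reruns.

## Known limitations

* Chi-square P-values of count-valued features are mildly discrete at
  small event counts; calibration holds per dataset (KS) and
  asymptotically, but pooling very many small-count P-values can reveal
  the discreteness.
* The importance score SC sums signed contributions; redundant signal
  carriers can split credit, so recovery is reported against a 2×
  planted-set cutoff rather than exact top-k.
* Dense mask matrices are appropriate at desk scale (thousands of nodes);
  a genome-scale Reactome build would want sparse storage.
* The GCN depth/width and the autoencoder objective are package choices;
  the decoder and 0.9 retention threshold are fixed by the method.
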