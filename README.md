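# pathlift

Pathway-hierarchy-constrained neural networks for predicting cancer
recurrence from multi-omics data, with graph-convolutional discovery of
latent pathway links and difference-from-reference attribution for global
gene/pathway importance.

## The problem

Post-surgical recurrence prediction from genomics (e.g. lung
adenocarcinoma cohorts) faces two obstacles: multi-omics matrices are
high-dimensional with few samples, and clinicians need to know *why* a
model predicts recurrence. `pathlift` addresses both by hard-wiring the
network's connectivity to a curated pathway hierarchy: a neuron exists for
each gene and each pathway entity, and a weight exists only where biology
says the entities interact. The model is sparse by construction and every
neuron has a biological name, so attribution scores read directly as gene
and pathway importance.

## The model

Omics features (binary somatic mutations SNV, and GISTIC-style copy-number
scores split into non-negative amplification AMP_CNV and deletion DEL_CNV
magnitudes) feed a gene stratum, then five pathway layers compiled from a
Reactome-style child→parent relation table. For layer *i* with binary
connectivity mask *Mᵢ*:

    X_{i+1} = tanh((Mᵢ ∘ Wᵢ)ᵀ Xᵢ + bᵢ),      ŷ = MLP(X₆) ∈ (0, 1)

and the class-imbalance-aware loss is

    L = (1/N) Σᵢ −[ w₁ yᵢ log ŷᵢ + w₀ (1−yᵢ) log(1−ŷᵢ) ]

with inverse-frequency weights w_c = N/(2 N_c) by default.

Two companions complete the framework:

* **Latent link augmentation** — a two-layer GCN autoencoder,
  H⁽ˡ⁺¹⁾ = σ(D̂^{−1/2}(A+I)D̂^{−1/2} H⁽ˡ⁾ W⁽ˡ⁾), with node features the
  pathways' gene memberships, scores unconnected adjacent-layer pairs with
  the inner-product decoder sigmoid(ĥᵤ·ĥᵥ); pairs scoring > 0.9 are added
  to the masks (the original topology is never removed).
* **Attribution** — each neuron is compared with its activation under the
  all-zero input (no aberrations); contributions propagate from the
  pre-sigmoid logit by the Rescale rule (multiplier Δout/Δin at each
  nonlinearity), conserving Σ C = t − t⁰ per layer. Global importance
  SC is the per-node sum over samples; genes are ranked by |SC|.

Evaluation is stratified 5-fold cross-validation repeated 5 times
reporting AUC, AUPR, accuracy and F1, with chi-square feature selection
and class weights refit inside each training fold.

## Worked example

`examples/02_train_and_evaluate.py` generates the reference synthetic
cohort — 505 samples, 134 recurrent (26.5%), 64 genes under a 5-layer
19-pathway hierarchy, 8 informative genes carrying a planted signal — and
cross-validates the masked network:

```
cohort: 505 samples, 134 recurrent; planted genes: ['G0001', 'G0009', ...]
model input: 505 samples x 192 features (SNV + AMP_CNV + DEL_CNV)
  auc       0.984 +/- 0.011
  aupr      0.963 +/- 0.025
  accuracy  0.947 +/- 0.027
  f1        0.898 +/- 0.052
```

Held-out AUC/AUPR near 1 means the network recovers the planted
gene→pathway signal. `examples/04_explain_predictions.py` then ranks genes
by attribution:

```
  rank  1  G0017  SC=+168.47 <- planted
  rank  2  G0001  SC=+166.20 <- planted
  ...
planted-gene ranks: [1, 2, 3, 4, 5, 6, 7, 8] (all within top 16 -> recovered)
```

All eight planted genes surface at the very top of the gene stratum —
the interpretability loop closes end to end. The other examples show mask
compilation from relation/GMT files and GCN link augmentation. A thin CLI
(`pathlift simulate|preprocess|train|augment|explain|evaluate`) wraps the
same functions for shell use.

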