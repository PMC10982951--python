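"""Train the pathway-masked network and cross-validate it.

Generates the reference synthetic cohort (505 samples, 26.5% recurrence,
8 informative genes), preprocesses it (noise filter, CNV sign-split,
chi-square selection), and runs stratified 5-fold CV repeated twice.
"""

import numpy as np

from pathlift import (SyntheticSpec, TrainConfig, compute_metrics,
                      cross_validate_pipeline, forward, make_study,
                      preprocess_blocks, train)
from pathlift.pipeline import prepare_inputs

spec = SyntheticSpec(seed=0)
hier, snv, cnv, labels, planted = make_study(spec)
print(f"cohort: {len(labels)} samples, {labels.sum()} recurrent; "
      f"planted genes: {planted}")

blocks = preprocess_blocks(snv, cnv, labels)
X, y, sample_ids, masks = prepare_inputs(blocks, hier)
print(f"model input: {X.shape[0]} samples x {X.shape[1]} features "
      f"(SNV + AMP_CNV + DEL_CNV)")

cv = cross_validate_pipeline([blocks[k] for k in ("SNV", "AMP_CNV", "DEL_CNV")],
                             y, hier, config=TrainConfig(seed=0),
                             folds=5, repeats=2, seed=0)
for m in ("auc", "aupr", "accuracy", "f1"):
    s = cv.summary[m]
    print(f"  {m:9s} {s['mean']:.3f} +/- {s['sd']:.3f}")
# Held-out AUC near 1 means the masked network recovers the planted
# gene->pathway signal; AUPR is the imbalance-robust headline metric.

params, log = train(X, y, masks, TrainConfig(seed=0))
m = compute_metrics(y, forward(X, masks, params))
print(f"final model (all data): training AUC {m['auc']:.3f}, "
      f"loss {log['train_loss'][-1]:.4f} after {len(log['train_loss'])} epochs")
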