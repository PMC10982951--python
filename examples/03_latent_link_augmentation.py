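"""Discover latent pathway links with the GCN autoencoder.

Trains a two-layer graph convolutional encoder on the pathway graph (node
features = gene memberships), scores every unconnected adjacent-layer pair
with the sigmoid inner-product decoder, and adds links scoring > 0.9 to the
masks without ever removing an original connection.
"""

import numpy as np

from pathlift import (SyntheticSpec, augment_masks, build_masks,
                      fit_link_model, layerize, make_hierarchy, score_links)

spec = SyntheticSpec(seed=0)
edges, gene_sets = make_hierarchy(spec)
hier = layerize(edges, gene_sets)
genes = sorted(set().union(*hier.gene_sets.values()))
masks = build_masks(hier, [(f"{g}|SNV", g, "SNV") for g in genes])

state, emb = fit_link_model(hier, seed=0)
print(f"embedded {len(state.node_ids)} pathway nodes in {emb.shape[1]} dims")

known = [score_links(emb[state.node_ids.index(c)], emb[state.node_ids.index(p)])
         for c, p in sorted(hier.edges)[:5]]
print("decoder scores for 5 known edges:", np.round(known, 3))

for thr in (0.5, 0.7, 0.9):
    aug, ledger = augment_masks(masks, hier, emb, threshold=thr,
                                node_ids=state.node_ids)
    print(f"threshold {thr}: {len(ledger)} latent link(s) added")
    for e in ledger[:3]:
        print(f"   {e['source']} -> {e['target']} (score {e['score']:.3f})")
# Only links above the retention threshold enter the masks; raising the
# threshold can only shrink the set of additions (monotonicity contract).
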