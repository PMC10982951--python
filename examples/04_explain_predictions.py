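"""Rank genes and pathways by difference-from-reference attribution.

Trains the masked network on the reference synthetic cohort, propagates
each sample's difference from the all-zero reference (no aberrations)
through the network with the Rescale rule, sums contributions over samples,
and ranks gene-stratum nodes by |SC|.  The planted informative genes should
surface at the top.
"""

import numpy as np

from pathlift import rank_nodes, run_study

res = run_study(seed=0, folds=5, repeats=2)
table = res["importance"]

print(f"reference logit (all-zero input): {table.reference_logit:.4f}")
top = rank_nodes(table, "gene").head(10)
planted = set(res["planted_genes"])
for _, row in top.iterrows():
    mark = " <- planted" if row["node"] in planted else ""
    print(f"  rank {int(row['rank']):2d}  {row['node']}  SC={row['sc']:+.2f}{mark}")

ranks = res["planted_gene_ranks"]
print(f"planted-gene ranks: {sorted(ranks.values())} "
      f"(all within top {2 * len(planted)} -> recovered)"
      if max(ranks.values()) <= 2 * len(planted) else
      f"planted-gene ranks: {sorted(ranks.values())}")

pw = rank_nodes(table, "pathway_1").head(3)
print("top layer-1 pathways:", ", ".join(
    f"{r['node']} (SC={r['sc']:+.2f})" for _, r in pw.iterrows()))
# SC sums signed per-sample contributions; genes whose aberrations push
# the recurrence logit consistently get large |SC|.
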