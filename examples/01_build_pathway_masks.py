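"""Build connectivity masks from a pathway relation table and gene sets.

Writes a small synthetic hierarchy to disk in the Reactome-style dialects
(child<TAB>parent TSV + GMT), parses it back, layers it into five strata,
and compiles the binary masks that later constrain the network's weights.
"""

import tempfile
from pathlib import Path

from pathlift import (SyntheticSpec, build_masks, layerize, parse_gene_sets,
                      parse_relations, write_hierarchy_files)

with tempfile.TemporaryDirectory() as tmp:
    rel, gmt = write_hierarchy_files(SyntheticSpec(seed=0), tmp)
    edges = parse_relations(rel)
    gene_sets = parse_gene_sets(gmt)
    print(f"parsed {len(edges)} relations, {len(gene_sets)} gene sets")

    hier = layerize(edges, gene_sets, depth=5)
    widths = [len(hier.layer_nodes(i)) for i in range(1, 6)]
    print(f"layer widths (leaf->root): {widths}; root set: {sorted(hier.root_set)}")

    genes = sorted(set().union(*hier.gene_sets.values()))
    table = ([(f"{g}|SNV", g, "SNV") for g in genes]
             + [(f"{g}|AMP_CNV", g, "AMP_CNV") for g in genes]
             + [(f"{g}|DEL_CNV", g, "DEL_CNV") for g in genes])
    masks = build_masks(hier, table)
    print("mask chain (rows x cols):", " -> ".join(str(m.shape) for m in masks.masks))
    nnz = int(sum(m.sum() for m in masks.masks))
    total = int(sum(m.size for m in masks.masks))
    print(f"{nnz} allowed connections out of {total} possible "
          f"({100 * nnz / total:.1f}% density)")
# Each mask's 1-entries are exactly the hierarchy's edges (or gene
# memberships); every neural connection outside them is forced to zero.
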