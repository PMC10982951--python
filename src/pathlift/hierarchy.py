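"""Pathway hierarchy parsing, layering, pruning and connectivity-mask compilation.

The model's connectivity is dictated by a curated pathway hierarchy (a
Reactome-style DAG of pathway entities).  The hierarchy is flattened into a
fixed number of layers (five by default); information flows from the most
specific, gene-carrying pathways (layer 1) up to root-adjacent pathways
(layer ``depth``).  Each adjacent layer pair is compiled into a binary mask
``M`` with ``M[j, k] = 1`` exactly when the hierarchy contains the edge
(node *j* at layer *i* -> node *k* at layer *i+1*); the mask later zeroes
every neural-network weight that has no pathway-level justification.

Two extra masks sit below the pathway layers: an omics-feature -> gene mask
and a gene -> layer-1-pathway membership mask, so genes form an explicit
stratum between the raw measurements and the hierarchy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayHierarchy",
    "MaskStack",
    "parse_relations",
    "parse_gene_sets",
    "layerize",
    "build_masks",
    "export_masks",
]


@dataclass
class PathwayHierarchy:
    """A layered DAG of pathway entities.

    Attributes
    ----------
    nodes : set of str
        Retained pathway identifiers.
    edges : set of (str, str)
        Directed child -> parent pairs; every retained edge connects
        consecutive layers (i -> i+1).
    layer_of : dict
        Node -> layer index in ``1..depth``; layer 1 holds the gene-carrying
        pathways, layer ``depth`` the root-adjacent ones.
    gene_sets : dict
        Layer-1 node -> set of gene symbols (uppercase).
    depth : int
        Number of pathway layers.
    """

    nodes: set[str]
    edges: set[tuple[str, str]]
    layer_of: dict[str, int]
    gene_sets: dict[str, set[str]]
    depth: int = 5

    @property
    def root_set(self) -> set[str]:
        """Top-layer entities that feed the prediction head."""
        return {n for n in self.nodes if self.layer_of[n] == self.depth}

    def layer_nodes(self, layer: int) -> list[str]:
        """Sorted identifiers of one layer."""
        return sorted(n for n in self.nodes if self.layer_of[n] == layer)

    def successors(self, node: str) -> set[str]:
        return {p for (c, p) in self.edges if c == node}

    def predecessors(self, node: str) -> set[str]:
        return {c for (c, p) in self.edges if p == node}

    def validate(self) -> None:
        """Assert the layered-DAG invariants; raise ``ValueError`` on violation."""
        g = nx.DiGraph(list(self.edges))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("hierarchy edge relation contains a cycle")
        for c, p in self.edges:
            if self.layer_of[p] != self.layer_of[c] + 1:
                raise ValueError(f"edge {c}->{p} skips layers")
        for n in self.nodes:
            lay = self.layer_of[n]
            if lay < self.depth and not self.successors(n):
                raise ValueError(f"node {n} (layer {lay}) has no successor")
            if lay > 1 and not self.predecessors(n):
                raise ValueError(f"node {n} (layer {lay}) has no predecessor")
            if lay == 1 and not self.gene_sets.get(n):
                raise ValueError(f"layer-1 node {n} has an empty gene set")


@dataclass
class MaskStack:
    """Binary connectivity masks chaining omics features to the top pathway layer.

    ``input_mask`` is features x genes, ``gene_mask`` genes x layer-1
    pathways, and ``pathway_masks[i]`` layer-(i+1) x layer-(i+2) pathways.
    ``node_index`` holds the ordered identifier list per stratum under the
    keys ``feature``, ``gene``, ``pathway_1`` ... ``pathway_<depth>``.
    """

    input_mask: np.ndarray
    gene_mask: np.ndarray
    pathway_masks: list[np.ndarray]
    node_index: dict[str, list[str]] = field(default_factory=dict)

    @property
    def masks(self) -> list[np.ndarray]:
        """All masks in forward order."""
        return [self.input_mask, self.gene_mask, *self.pathway_masks]

    @property
    def layer_names(self) -> list[str]:
        return ["feature", "gene"] + [f"pathway_{i + 1}" for i in range(len(self.pathway_masks) + 1)]

    def validate(self) -> None:
        for m in self.masks:
            vals = np.unique(m)
            if not np.isin(vals, [0.0, 1.0]).all():
                raise ValueError("mask entries must be binary")
            if (m.sum(axis=0) == 0).any():
                raise ValueError("mask contains an all-zero column")
        for a, b in zip(self.masks, self.masks[1:]):
            if a.shape[1] != b.shape[0]:
                raise ValueError(f"mask shapes do not chain: {a.shape} then {b.shape}")


def parse_relations(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column child<TAB>parent relation table.

    Lines starting with ``#`` are ignored.  Duplicate rows are collapsed,
    order of first appearance preserved.  A self-pair is rejected: the edge
    relation must stay acyclic.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    n_rows = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            child, parent = parts[0].strip(), parts[1].strip()
            if not child or not parent:
                raise ValueError(f"{path}:{lineno}: empty identifier")
            if child == parent:
                raise ValueError(f"{path}:{lineno}: self-loop {child!r}")
            n_rows += 1
            if (child, parent) not in seen:
                seen.add((child, parent))
                edges.append((child, parent))
    if n_rows == 0:
        raise ValueError(f"{path}: no relation rows found")
    return edges


def parse_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file (name, description, gene symbols...) into a mapping.

    Gene symbols are uppercased and deduplicated.  Repeated set names are
    merged by union with a warning.
    """
    path = Path(path)
    gene_sets: dict[str, set[str]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(parts)}")
            name = parts[0].strip()
            genes = {g.strip().upper() for g in parts[2:] if g.strip()}
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in gene_sets:
                logger.warning("gene set %r repeated; taking union", name)
                gene_sets[name] |= genes
            else:
                gene_sets[name] = genes
    if not gene_sets:
        raise ValueError(f"{path}: no gene sets found")
    return gene_sets


def _assign_layers(
    edges: set[tuple[str, str]], leaf_ok: set[str]
) -> dict[str, int]:
    """Layer = 1 + shortest distance from an admissible in-degree-0 node."""
    g = nx.DiGraph(list(edges))
    leaves = [n for n in g.nodes if g.in_degree(n) == 0 and n in leaf_ok]
    layer: dict[str, int] = {}
    frontier = list(leaves)
    for n in frontier:
        layer[n] = 1
    while frontier:
        nxt = []
        for n in frontier:
            for _, p in g.out_edges(n):
                if p not in layer:
                    layer[p] = layer[n] + 1
                    nxt.append(p)
        frontier = nxt
    return layer


def layerize(
    edges: Iterable[tuple[str, str]],
    gene_sets: Mapping[str, Iterable[str]],
    depth: int = 5,
) -> PathwayHierarchy:
    """Flatten an acyclic child->parent relation into ``depth`` strict layers.

    A node's layer is its minimum distance from the gene-carrying leaves
    (layer 1 = distance 0).  The pruning loop removes, until a fixed point:

    * layer-1 candidates without a gene set,
    * nodes whose layer exceeds ``depth`` or that are unreachable from a
      gene-carrying leaf,
    * edges that skip layers,
    * nodes below the top layer left without a successor, and nodes above
      layer 1 left without a predecessor.

    Raises ``ValueError`` when no ``depth``-layer backbone survives.
    """
    gene_sets = {k: {str(g).upper() for g in v} for k, v in gene_sets.items() if v}
    edges_set = {(str(c), str(p)) for c, p in edges}
    g = nx.DiGraph(list(edges_set))
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("relation is not acyclic")

    leaf_ok = set(gene_sets)
    while True:
        changed = False
        layer = _assign_layers(edges_set, leaf_ok)
        nodes = {n for n, l in layer.items() if l <= depth}
        dropped = {n for n in {c for c, _ in edges_set} | {p for _, p in edges_set}} - nodes
        if dropped:
            pass  # unreachable or too-deep nodes fall out with their edges
        kept_edges = {
            (c, p)
            for (c, p) in edges_set
            if c in nodes and p in nodes and layer[p] == layer[c] + 1
        }
        if kept_edges != edges_set:
            changed = True
        # successor / predecessor fixed-point rules
        while True:
            succ_fail = {
                n for n in nodes
                if layer[n] < depth and not any(c == n for c, _ in kept_edges)
            }
            pred_fail = {
                n for n in nodes
                if layer[n] > 1 and not any(p == n for _, p in kept_edges)
            }
            no_genes = {n for n in nodes if layer[n] == 1 and n not in gene_sets}
            bad = succ_fail | pred_fail | no_genes
            if not bad:
                break
            changed = True
            if no_genes:
                logger.warning("dropping %d layer-1 node(s) without gene sets", len(no_genes))
            nodes -= bad
            kept_edges = {(c, p) for (c, p) in kept_edges if c not in bad and p not in bad}
        if not changed:
            break
        edges_set = kept_edges
        # nodes dropped from layer 1 must not reappear as leaves
        leaf_ok = {n for n in nodes if layer[n] == 1}
        if not nodes:
            break

    layer = {n: l for n, l in layer.items() if n in nodes}
    if not nodes or max(layer.values(), default=0) < depth:
        raise ValueError(f"no {depth}-layer backbone after pruning")
    hier = PathwayHierarchy(
        nodes=set(nodes),
        edges=set(kept_edges),
        layer_of=layer,
        gene_sets={n: set(gene_sets[n]) for n in nodes if layer[n] == 1},
        depth=depth,
    )
    hier.validate()
    return hier


def build_masks(
    hier: PathwayHierarchy,
    feature_table: Sequence[tuple[str, str, str]],
) -> MaskStack:
    """Compile the binary connectivity masks for a layered hierarchy.

    ``feature_table`` rows are ``(feature_id, gene_symbol, omics_type)`` with
    ``omics_type`` in {SNV, AMP_CNV, DEL_CNV}.  Genes not present in any
    retained layer-1 pathway are dropped (logged); layer-1 pathways whose
    gene sets lose every gene trigger a re-prune so no mask column is left
    all-zero.
    """
    feature_table = list(feature_table)
    if not feature_table:
        raise ValueError("empty feature table")
    feat_gene = {f: g.upper() for f, g, _ in feature_table}
    measured_genes = set(feat_gene.values())

    pathway_gene_union = set().union(*hier.gene_sets.values()) if hier.gene_sets else set()
    genes = sorted(measured_genes & pathway_gene_union)
    if not genes:
        raise ValueError("no overlap between feature genes and pathway genes")
    n_unmapped = len(measured_genes - pathway_gene_union)
    if n_unmapped:
        logger.info("dropping %d measured gene(s) absent from pathway gene sets", n_unmapped)

    # restrict gene sets to measured genes; re-prune if any layer-1 set empties
    restricted = {p: gs & set(genes) for p, gs in hier.gene_sets.items()}
    if any(not gs for gs in restricted.values()):
        hier = layerize(hier.edges, {p: gs for p, gs in restricted.items() if gs}, hier.depth)
        restricted = hier.gene_sets

    features = [f for f, g, _ in feature_table if feat_gene[f] in set(genes)]
    gene_pos = {g: i for i, g in enumerate(genes)}
    input_mask = np.zeros((len(features), len(genes)))
    for i, f in enumerate(features):
        input_mask[i, gene_pos[feat_gene[f]]] = 1.0

    layer1 = hier.layer_nodes(1)
    gene_mask = np.zeros((len(genes), len(layer1)))
    for j, p in enumerate(layer1):
        for g in restricted[p]:
            gene_mask[gene_pos[g], j] = 1.0

    node_index = {"feature": features, "gene": genes, "pathway_1": layer1}
    pathway_masks = []
    for lay in range(1, hier.depth):
        lower = hier.layer_nodes(lay)
        upper = hier.layer_nodes(lay + 1)
        m = np.zeros((len(lower), len(upper)))
        lo = {n: i for i, n in enumerate(lower)}
        up = {n: i for i, n in enumerate(upper)}
        for c, p in hier.edges:
            if hier.layer_of[c] == lay:
                m[lo[c], up[p]] = 1.0
        pathway_masks.append(m)
        node_index[f"pathway_{lay + 1}"] = upper

    stack = MaskStack(input_mask, gene_mask, pathway_masks, node_index)
    stack.validate()
    return stack


def export_masks(stack: MaskStack, out_dir: str | Path) -> None:
    """Write each mask as a sparse triplet TSV plus a JSON manifest of node orders."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = stack.layer_names
    for k, m in enumerate(stack.masks):
        rows_ids = stack.node_index[names[k]]
        col_ids = stack.node_index[names[k + 1]]
        with (out_dir / f"mask_{names[k]}_to_{names[k + 1]}.tsv").open("w") as fh:
            fh.write("row_id\tcol_id\tvalue\n")
            for r, c in zip(*np.nonzero(m)):
                fh.write(f"{rows_ids[r]}\t{col_ids[c]}\t1\n")
    with (out_dir / "masks_manifest.json").open("w") as fh:
        json.dump({"layers": names, "node_index": stack.node_index}, fh, indent=1)
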