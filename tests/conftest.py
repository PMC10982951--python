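"""Shared fixtures: tiny hand-built mask stacks and random small hierarchies."""

from __future__ import annotations

import numpy as np
import pytest

from pathlift.hierarchy import MaskStack, PathwayHierarchy, build_masks, layerize
from pathlift.network import MaskedNetParams, init_params


def chain_maskstack(n_pathway_layers: int = 5) -> MaskStack:
    """1 feature -> 1 gene -> one node per pathway layer, all connected."""
    one = np.ones((1, 1))
    node_index = {"feature": ["F0"], "gene": ["G0"]}
    for i in range(n_pathway_layers):
        node_index[f"pathway_{i + 1}"] = [f"P{i + 1}"]
    return MaskStack(one.copy(), one.copy(),
                     [one.copy() for _ in range(n_pathway_layers - 1)], node_index)


def random_hierarchy(rng: np.random.Generator, widths=(3, 3, 2, 2, 1),
                     density: float = 0.6):
    """Random layered DAG (edges, gene_sets) guaranteed unprunable."""
    names = [[f"L{l + 1}N{j}" for j in range(w)] for l, w in enumerate(widths)]
    edges = []
    for l in range(len(widths) - 1):
        lower, upper = names[l], names[l + 1]
        covered = set()
        for c in lower:
            succ = [u for u in upper if rng.random() < density]
            if not succ:
                succ = [upper[rng.integers(len(upper))]]
            edges += [(c, u) for u in succ]
            covered.update(succ)
        for u in upper:
            if u not in covered:
                edges.append((lower[rng.integers(len(lower))], u))
    gene_sets = {leaf: {f"GENE{l}_{leaf}" for l in range(2)} for leaf in names[0]}
    return edges, gene_sets


def hierarchy_with_masks(rng: np.random.Generator, widths=(3, 3, 2, 2, 1)):
    """Layerized hierarchy plus masks over one SNV feature per gene."""
    edges, gene_sets = random_hierarchy(rng, widths)
    hier = layerize(edges, gene_sets, depth=len(widths))
    genes = sorted(set().union(*hier.gene_sets.values()))
    table = [(f"{g}|SNV", g, "SNV") for g in genes]
    return hier, build_masks(hier, table)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_stack() -> MaskStack:
    return chain_maskstack()


@pytest.fixture
def small_model(rng):
    """A random small hierarchy, its masks, and initialized parameters."""
    hier, masks = hierarchy_with_masks(rng)
    params = init_params(masks, seed=3)
    return hier, masks, params
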