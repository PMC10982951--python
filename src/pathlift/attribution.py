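"""Global node-importance scoring by difference-from-reference attribution.

Each neuron's activation is compared with its activation under an all-zero
input (the reference: absence of any genomic aberration).  Contributions are
propagated from the pre-sigmoid output logit back to every node with the
Rescale rule: linear (masked) connections distribute contribution in
proportion to ``weight x delta-input``; each nonlinearity carries the
elementwise multiplier ``delta-out / delta-in`` (gradient fallback when
``|delta-in|`` is tiny).  The rule conserves the output difference at every
layer — the summation-to-delta property:

    sum_nodes C(layer) = t - t0        for every layer and sample.

Global importance is the per-node sum of contributions over a sample set,
used to rank genes and pathway entities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import MaskStack, PathwayHierarchy
from .network import MaskedNetParams, _act, forward

logger = logging.getLogger(__name__)

__all__ = [
    "ImportanceTable",
    "reference_forward",
    "deeplift_rescale",
    "attribute_samples",
    "aggregate_global",
    "rank_nodes",
    "export_scores",
]

_DELTA_EPS = 1e-7


@dataclass
class ImportanceTable:
    """Per-sample and aggregated node contributions, keyed by stratum name."""

    per_sample: dict[str, np.ndarray]          # layer -> (n_samples, n_nodes)
    global_scores: dict[str, np.ndarray]       # layer -> (n_nodes,)
    node_index: dict[str, list[str]]
    sample_ids: list[str]
    reference_logit: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def layers(self) -> list[str]:
        return list(self.per_sample)


def reference_forward(masks: MaskStack, params: MaskedNetParams):
    """Forward pass on the all-zero input; returns ``(prob, cache)``.

    The cache holds every neuron's reference activation, including the head.
    References are sample-independent and computed once per model.
    """
    x0 = np.zeros((1, masks.input_mask.shape[0]))
    return forward(x0, masks, params, return_intermediates=True)


def _rescale_multiplier(dz: np.ndarray, da: np.ndarray, z: np.ndarray, dact) -> np.ndarray:
    """Elementwise Rescale multiplier delta-a / delta-z with gradient fallback."""
    small = np.abs(dz) < _DELTA_EPS
    safe = np.where(small, 1.0, dz)
    return np.where(small, dact(z), da / safe)


def deeplift_rescale(
    x: np.ndarray,
    masks: MaskStack,
    params: MaskedNetParams,
    reference=None,
    mode: str = "rescale",
) -> dict[str, np.ndarray]:
    """Contributions of every node to the pre-sigmoid logit for sample(s) ``x``.

    Accepts a single sample or a batch (rows).  Returns a mapping stratum
    name ('feature', 'gene', 'pathway_1', ..., 'hidden') -> contribution
    array of shape (n_samples, n_nodes), satisfying summation-to-delta per
    stratum.  ``mode='gradient_times_delta'`` is a diagnostic variant that
    scores inputs by ``(dt/dx) * (t - t0)``; it does not conserve the delta.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != masks.input_mask.shape[0]:
        raise ValueError("sample dimension does not match the input mask")
    if reference is None:
        reference = reference_forward(masks, params)
    _, ref = reference
    _, cache = forward(x, masks, params, return_intermediates=True)
    _, dact = _act(params.activation)

    names = masks.layer_names  # feature, gene, pathway_1..pathway_D
    d_as = [a - r for a, r in zip(cache["as"], ref["as"])]
    d_zs = [z - r for z, r in zip(cache["zs"], ref["zs"])]
    d_zh = cache["zh"] - ref["zh"]
    d_ah = cache["ah"] - ref["ah"]
    d_logit = cache["logit"] - ref["logit"]

    if mode == "gradient_times_delta":
        # literal gradient-times-delta diagnostic: C = (dt/da) * (t - t0).
        # Not conservative; kept only for comparison with the Rescale rule.
        out: dict[str, np.ndarray] = {}
        g_a = np.broadcast_to(params.head_w2, d_ah.shape).copy()  # dt/d a_hidden
        out["hidden"] = g_a * d_logit[:, None]
        g_a = (g_a * dact(cache["zh"])) @ params.head_w1.T
        for k in range(len(masks.masks) - 1, -1, -1):
            out[names[k + 1]] = g_a * d_logit[:, None]
            g_z = g_a * dact(cache["zs"][k])
            g_a = g_z @ (masks.masks[k] * params.layer_weights[k]).T
        out["feature"] = g_a * d_logit[:, None]
        return out
    if mode != "rescale":
        raise ValueError(f"unknown attribution mode {mode!r}")

    contributions: dict[str, np.ndarray] = {}
    # multiplier from hidden activations to the logit (linear head output)
    r_ah = np.broadcast_to(params.head_w2, d_ah.shape).copy()
    contributions["hidden"] = d_ah * r_ah
    m_h = _rescale_multiplier(d_zh, d_ah, ref["zh"], dact)
    r_zh = r_ah * m_h
    # into the top masked activation layer
    r_a = r_zh @ params.head_w1.T
    for k in range(len(masks.masks) - 1, -1, -1):
        contributions[names[k + 1]] = d_as[k + 1] * r_a
        m_k = _rescale_multiplier(d_zs[k], d_as[k + 1], ref["zs"][k], dact)
        r_z = r_a * m_k
        r_a = r_z @ (masks.masks[k] * params.layer_weights[k]).T
    contributions["feature"] = (x - np.zeros_like(x)) * r_a

    # conservation check (cheap, catches shape/rule regressions early)
    for name, c in contributions.items():
        s = c.sum(axis=1)
        denom = np.maximum(np.abs(d_logit), 1e-12)
        if np.max(np.abs(s - d_logit) / denom) > 1e-4:
            logger.debug("summation-to-delta drift in stratum %s", name)
    return contributions


def attribute_samples(
    X: np.ndarray, masks: MaskStack, params: MaskedNetParams,
    sample_ids: list[str] | None = None,
) -> ImportanceTable:
    """Attribute a whole matrix and aggregate into global importance scores."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    reference = reference_forward(masks, params)
    per_sample = deeplift_rescale(X, masks, params, reference=reference)
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(X.shape[0])]
    global_scores = {k: v.sum(axis=0) for k, v in per_sample.items()}
    node_index = dict(masks.node_index)
    node_index["hidden"] = [f"H{i}" for i in range(per_sample["hidden"].shape[1])]
    return ImportanceTable(
        per_sample=per_sample,
        global_scores=global_scores,
        node_index=node_index,
        sample_ids=list(sample_ids),
        reference_logit=float(reference[1]["logit"][0]),
    )


def aggregate_global(
    per_sample: dict[str, np.ndarray],
    sample_indices: np.ndarray | list[int] | None = None,
    labels: np.ndarray | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Sum contributions over a sample set: ``SC = sum_j C_j``.

    Also emits mean-|C| and, when labels are supplied, per-class sums
    (diagnostic extensions beyond the plain sum).
    """
    layers = list(per_sample)
    n = per_sample[layers[0]].shape[0]
    idx = np.arange(n) if sample_indices is None else np.asarray(sample_indices)
    if idx.size == 0:
        raise ValueError("empty sample set")
    out: dict[str, dict[str, np.ndarray]] = {}
    for name, c in per_sample.items():
        sub = c[idx]
        entry = {"sc": sub.sum(axis=0), "mean_abs": np.abs(sub).mean(axis=0)}
        if labels is not None:
            lab = np.asarray(labels)[idx]
            entry["sc_pos"] = sub[lab == 1].sum(axis=0)
            entry["sc_neg"] = sub[lab == 0].sum(axis=0)
        out[name] = entry
    return out


def rank_nodes(table: ImportanceTable, layer: str) -> pd.DataFrame:
    """Nodes of one stratum ordered by descending |SC|; ties by node id."""
    if layer not in table.global_scores:
        raise KeyError(f"unknown layer {layer!r}; have {list(table.global_scores)}")
    sc = table.global_scores[layer]
    ids = table.node_index[layer]
    order = sorted(range(len(ids)), key=lambda i: (-abs(sc[i]), ids[i]))
    return pd.DataFrame({
        "node": [ids[i] for i in order],
        "sc": [sc[i] for i in order],
        "rank": np.arange(1, len(ids) + 1),
    })


def export_scores(
    table: ImportanceTable,
    masks: MaskStack,
    out_dir: str | Path,
    hierarchy: PathwayHierarchy | None = None,
) -> None:
    """Write per-layer score TSVs and a JSON graph for network visualization.

    The JSON nodes carry SC scores; edges are the nonzeros of the (possibly
    augmented) masks, so edge count equals total mask nnz.  Floats are
    written with full round-trip precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    strata = [n for n in masks.layer_names if n in table.global_scores]
    for name in strata:
        df = rank_nodes(table, name)
        with (out_dir / f"scores_{name}.tsv").open("w") as fh:
            fh.write("layer\tnode\tsc\trank\n")
            for _, row in df.iterrows():
                fh.write(f"{name}\t{row['node']}\t{row['sc']!r}\t{int(row['rank'])}\n")
    nodes = []
    for name in strata:
        sc = table.global_scores[name]
        for i, nid in enumerate(table.node_index[name]):
            nodes.append({"id": f"{name}:{nid}", "layer": name, "sc": sc[i]})
    edges = []
    names = masks.layer_names
    for k, m in enumerate(masks.masks):
        rows = table.node_index[names[k]] if names[k] in table.node_index else masks.node_index[names[k]]
        cols = masks.node_index[names[k + 1]]
        for r, c in zip(*np.nonzero(m)):
            edges.append({"source": f"{names[k]}:{rows[r]}", "target": f"{names[k + 1]}:{cols[c]}"})
    with (out_dir / "importance_graph.json").open("w") as fh:
        json.dump({"nodes": nodes, "edges": edges}, fh, indent=1)
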