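"""Latent pathway-link discovery: GCN graph autoencoder over the hierarchy.

Pathway entities are nodes of an undirected view of the hierarchy; each
node's feature vector is the binary membership of its (descendant-propagated)
gene set over a fixed gene vocabulary.  A two-layer graph convolutional
encoder

    H^(l+1) = sigma( D^{-1/2} (A + I) D^{-1/2} H^(l) W^(l) )

(ReLU hidden, linear output) is trained to reconstruct the known edges with
an inner-product decoder, ``p(u ~ v) = sigmoid(h_u . h_v)``, against
uniformly sampled non-edges.  Candidate links between consecutive layers
scoring above a retention threshold (0.9) are then added to the connectivity
masks; the original topology is never removed, only augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam
from .hierarchy import MaskStack, PathwayHierarchy

__all__ = [
    "GCNState",
    "build_node_features",
    "normalized_adjacency",
    "gcn_layer",
    "train_gcn",
    "fit_link_model",
    "score_links",
    "augment_masks",
]


@dataclass
class GCNState:
    """Node features, adjacency and encoder weights for the pathway graph."""

    H: np.ndarray                     # nodes x gene-vocabulary, binary
    A: np.ndarray                     # symmetric adjacency, zero diagonal
    node_ids: list[str]
    W: list[np.ndarray] = field(default_factory=list)
    embeddings: np.ndarray | None = None


def build_node_features(hier: PathwayHierarchy, gene_vocab: list[str] | None = None
                        ) -> tuple[np.ndarray, list[str], list[str]]:
    """Binary gene-membership features per pathway node.

    Layer-1 nodes carry their own gene sets; higher layers the union of
    their descendants' sets (propagated upward).  Returns ``(H, node_ids,
    gene_vocab)``; an all-zero row is an error (the node should have been
    pruned).
    """
    if gene_vocab is None:
        gene_vocab = sorted(set().union(*hier.gene_sets.values()))
    pos = {g: i for i, g in enumerate(gene_vocab)}
    genes_of: dict[str, set[str]] = {}
    for lay in range(1, hier.depth + 1):
        for n in hier.layer_nodes(lay):
            if lay == 1:
                genes_of[n] = set(hier.gene_sets[n])
            else:
                genes_of[n] = set().union(*(genes_of[c] for c in hier.predecessors(n)))
    node_ids = [n for lay in range(1, hier.depth + 1) for n in hier.layer_nodes(lay)]
    H = np.zeros((len(node_ids), len(gene_vocab)))
    for i, n in enumerate(node_ids):
        cols = [pos[g] for g in genes_of[n] if g in pos]
        if not cols:
            raise ValueError(f"node {n} has an empty propagated gene set")
        H[i, cols] = 1.0
    return H, node_ids, gene_vocab


def normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^{-1/2} (A + I) D^{-1/2}."""
    A = np.asarray(A, dtype=float)
    if A.shape[0] != A.shape[1] or not np.allclose(A, A.T):
        raise ValueError("adjacency must be square and symmetric")
    At = A + np.eye(A.shape[0])
    d = At.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return At * dinv[:, None] * dinv[None, :]


def gcn_layer(H: np.ndarray, A: np.ndarray, W: np.ndarray,
              activation: str = "relu") -> np.ndarray:
    """One graph convolution over the raw adjacency ``A`` (self-loops added here)."""
    S = normalized_adjacency(A)
    out = S @ H @ W
    if activation == "relu":
        return np.maximum(out, 0.0)
    if activation in ("identity", "linear"):
        return out
    raise ValueError(f"unknown activation {activation!r}")


def _adjacency(hier: PathwayHierarchy, node_ids: list[str]) -> np.ndarray:
    pos = {n: i for i, n in enumerate(node_ids)}
    A = np.zeros((len(node_ids), len(node_ids)))
    for c, p in hier.edges:
        A[pos[c], pos[p]] = 1.0
        A[pos[p], pos[c]] = 1.0
    return A


def train_gcn(state: GCNState, epochs: int = 200, neg_ratio: float = 1.0,
              seed: int = 0, hidden_dim: int = 64, embed_dim: int = 32,
              lr: float = 1e-2) -> np.ndarray:
    """Train the two-layer GCN autoencoder; returns node embeddings.

    Positives are the known undirected edges; negatives are sampled
    uniformly (seeded) from the non-edges at ``neg_ratio`` per positive.
    Loss is binary cross-entropy on the sigmoid inner-product scores.
    """
    rng = np.random.default_rng(seed)
    H, A = state.H, state.A
    m = H.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    pos_mask = A[iu, ju] > 0
    pos_pairs = np.stack([iu[pos_mask], ju[pos_mask]], axis=1)
    neg_pool = np.stack([iu[~pos_mask], ju[~pos_mask]], axis=1)
    if len(pos_pairs) == 0:
        raise ValueError("graph has no edges")
    if len(neg_pool) == 0:
        raise ValueError("graph has no non-edges to sample negatives from")

    S = normalized_adjacency(A)
    n_feat = H.shape[1]
    w0 = rng.normal(0, np.sqrt(2.0 / n_feat), size=(n_feat, hidden_dim))
    w1 = rng.normal(0, np.sqrt(2.0 / hidden_dim), size=(hidden_dim, embed_dim))
    opt = Adam([w0, w1], lr=lr)
    n_neg = max(1, int(round(neg_ratio * len(pos_pairs))))

    for _ in range(epochs):
        neg_pairs = neg_pool[rng.integers(0, len(neg_pool), size=n_neg)]
        pairs = np.vstack([pos_pairs, neg_pairs])
        labels = np.concatenate([np.ones(len(pos_pairs)), np.zeros(len(neg_pairs))])

        h1pre = S @ H @ w0
        h1 = np.maximum(h1pre, 0.0)
        Z = S @ h1 @ w1

        u, v = pairs[:, 0], pairs[:, 1]
        logits = np.einsum("ij,ij->i", Z[u], Z[v])
        p = 1.0 / (1.0 + np.exp(-logits))
        g = (p - labels) / len(labels)

        dZ = np.zeros_like(Z)
        np.add.at(dZ, u, g[:, None] * Z[v])
        np.add.at(dZ, v, g[:, None] * Z[u])
        Sh1 = S @ h1
        g_w1 = Sh1.T @ dZ
        dh1 = S @ (dZ @ w1.T)
        dh1pre = dh1 * (h1pre > 0)
        g_w0 = (S @ H).T @ dh1pre
        opt.step([g_w0, g_w1])

    h1 = np.maximum(S @ H @ w0, 0.0)
    Z = S @ h1 @ w1
    state.W = [w0, w1]
    state.embeddings = Z
    return Z


def fit_link_model(hier: PathwayHierarchy, epochs: int = 200, neg_ratio: float = 1.0,
                   seed: int = 0, embed_dim: int = 32) -> tuple[GCNState, np.ndarray]:
    """Convenience: build features + adjacency from a hierarchy and train."""
    H, node_ids, _ = build_node_features(hier)
    A = _adjacency(hier, node_ids)
    state = GCNState(H=H, A=A, node_ids=node_ids)
    emb = train_gcn(state, epochs=epochs, neg_ratio=neg_ratio, seed=seed,
                    embed_dim=embed_dim)
    return state, emb


def score_links(emb_u: np.ndarray, emb_v: np.ndarray) -> float | np.ndarray:
    """Sigmoid of the inner product of two embeddings (symmetric in u, v)."""
    emb_u = np.asarray(emb_u, dtype=float)
    emb_v = np.asarray(emb_v, dtype=float)
    if emb_u.shape[-1] != emb_v.shape[-1]:
        raise ValueError("embedding dimension mismatch")
    dot = np.sum(emb_u * emb_v, axis=-1)
    out = 1.0 / (1.0 + np.exp(-dot))
    return float(out) if np.ndim(out) == 0 else out


def augment_masks(
    masks: MaskStack,
    hier: PathwayHierarchy,
    embeddings: dict[str, np.ndarray] | np.ndarray,
    threshold: float = 0.9,
    node_ids: list[str] | None = None,
) -> tuple[MaskStack, list[dict]]:
    """Add high-scoring latent links between consecutive pathway layers.

    For every adjacent-layer pair of pathway nodes not already connected, a
    mask entry is added iff ``sigmoid(h_u . h_v) > threshold`` (strictly).
    Original entries are never removed.  Returns the augmented stack and a
    ledger of added links ``{source, target, layer_pair, score}``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if not isinstance(embeddings, dict):
        if node_ids is None:
            raise ValueError("node_ids required when embeddings is an array")
        embeddings = {n: embeddings[i] for i, n in enumerate(node_ids)}

    new_pathway_masks = [m.copy() for m in masks.pathway_masks]
    ledger: list[dict] = []
    for k, m in enumerate(new_pathway_masks):
        lower = masks.node_index[f"pathway_{k + 1}"]
        upper = masks.node_index[f"pathway_{k + 2}"]
        for i, u in enumerate(lower):
            for j, v in enumerate(upper):
                if m[i, j] == 1.0:
                    continue
                s = score_links(embeddings[u], embeddings[v])
                if s > threshold:
                    m[i, j] = 1.0
                    ledger.append({"source": u, "target": v,
                                   "layer_pair": f"{k + 1}->{k + 2}", "score": float(s)})
    out = MaskStack(masks.input_mask.copy(), masks.gene_mask.copy(),
                    new_pathway_masks, dict(masks.node_index))
    for orig, aug in zip(masks.pathway_masks, out.pathway_masks):
        assert ((aug - orig) >= 0).all() and aug.sum() >= orig.sum(), \
            "augmentation must preserve the original topology"
    return out, ledger
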