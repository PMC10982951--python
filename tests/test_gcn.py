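"""GCN encoder, inner-product link scoring and mask augmentation."""

import numpy as np
import pytest

from pathlift.gcn import (GCNState, augment_masks, build_node_features,
                          fit_link_model, gcn_layer, normalized_adjacency,
                          score_links, train_gcn)
from pathlift.hierarchy import layerize

from conftest import hierarchy_with_masks, random_hierarchy


def _dense_oracle(H, A, W, relu=True):
    """Independent dense construction of D^{-1/2}(A+I)D^{-1/2} H W."""
    At = A + np.eye(A.shape[0])
    D = np.diag(At.sum(axis=1))
    Dm = np.linalg.inv(np.sqrt(D))
    out = Dm @ At @ Dm @ H @ W
    return np.maximum(out, 0) if relu else out


# ---------------------------------------------------------------- features

def _chain_hier():
    return layerize([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")],
                    {"a": {"G1", "G3"}})


def test_membership_row_over_vocab():
    h = _chain_hier()
    H, node_ids, vocab = build_node_features(h, gene_vocab=["G1", "G2", "G3"])
    np.testing.assert_array_equal(H[node_ids.index("a")], [1, 0, 1])


def test_parent_features_are_union_of_children():
    edges = [("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f")]
    h = layerize(edges, {"a": {"G1"}, "b": {"G2"}})
    H, node_ids, vocab = build_node_features(h)
    a, b, c = (H[node_ids.index(n)] for n in "abc")
    np.testing.assert_array_equal(c, np.maximum(a, b))  # elementwise OR


def test_vocab_permutation_permutes_columns_only():
    h = _chain_hier()
    H1, ids1, _ = build_node_features(h, gene_vocab=["G1", "G3"])
    H2, ids2, _ = build_node_features(h, gene_vocab=["G3", "G1"])
    assert ids1 == ids2
    np.testing.assert_array_equal(H1, H2[:, ::-1])


# ---------------------------------------------------------------- gcn_layer

def test_gcn_layer_single_node_degenerates_to_dense():
    H = np.array([[1.0, -2.0]])
    W = np.array([[0.5, 1.0], [2.0, -1.0]])
    out = gcn_layer(H, np.zeros((1, 1)), W)
    np.testing.assert_allclose(out, np.maximum(H @ W, 0))


def test_gcn_layer_two_nodes_hand_oracle():
    """One edge, self-loops make both degrees 2; operator entries all 1/2."""
    A = np.array([[0.0, 1.0], [1.0, 0.0]])
    S = normalized_adjacency(A)
    np.testing.assert_allclose(S, np.full((2, 2), 0.5))
    H = np.array([[1.0], [3.0]])
    out = gcn_layer(H, A, np.eye(1), activation="identity")
    np.testing.assert_allclose(out, [[2.0], [2.0]])  # 0.5 * row-sums


@pytest.mark.parametrize("seed", range(10))
def test_gcn_layer_matches_dense_oracle_random_graphs(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    A = (rng.random((n, n)) < 0.4).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    H = rng.normal(size=(n, 3))
    W = rng.normal(size=(3, 4))
    np.testing.assert_allclose(gcn_layer(H, A, W), _dense_oracle(H, A, W),
                               atol=1e-12)


def test_gcn_layer_rejects_asymmetric_adjacency():
    with pytest.raises(ValueError, match="symmetric"):
        gcn_layer(np.ones((2, 1)), np.array([[0.0, 1.0], [0.0, 0.0]]), np.eye(1))


# ---------------------------------------------------------------- training

def test_train_gcn_is_deterministic(rng):
    hier, _ = hierarchy_with_masks(rng)
    _, emb1 = fit_link_model(hier, epochs=30, seed=9)
    _, emb2 = fit_link_model(hier, epochs=30, seed=9)
    np.testing.assert_array_equal(emb1, emb2)


def test_train_gcn_errors_without_negatives():
    # complete graph K3: every pair is an edge
    A = np.ones((3, 3)) - np.eye(3)
    state = GCNState(H=np.eye(3), A=A, node_ids=["a", "b", "c"])
    with pytest.raises(ValueError, match="non-edges"):
        train_gcn(state, epochs=2, neg_ratio=1.0, seed=0)


def test_train_gcn_errors_without_edges():
    state = GCNState(H=np.eye(3), A=np.zeros((3, 3)), node_ids=list("abc"))
    with pytest.raises(ValueError, match="no edges"):
        train_gcn(state, epochs=2, seed=0)


def test_two_cliques_rank_within_over_between(rng):
    """Held-out within-clique pairs outscore between-clique pairs."""
    n = 8
    A = np.zeros((n, n))
    for grp in (range(4), range(4, 8)):
        for i in grp:
            for j in grp:
                if i < j:
                    A[i, j] = A[j, i] = 1.0
    held = [(0, 1), (4, 5)]
    for i, j in held:
        A[i, j] = A[j, i] = 0.0
    H = np.zeros((n, 4))
    H[:4, :2] = rng.random((4, 2)) + 0.5
    H[4:, 2:] = rng.random((4, 2)) + 0.5
    wins = 0
    for seed in range(10):
        state = GCNState(H=H.copy(), A=A.copy(), node_ids=[str(i) for i in range(n)])
        Z = train_gcn(state, epochs=150, seed=seed)
        within = np.mean([score_links(Z[i], Z[j]) for i, j in held])
        between = np.mean([score_links(Z[i], Z[j]) for i in range(4) for j in range(4, 8)])
        wins += within > between
    assert wins >= 8


# ---------------------------------------------------------------- scoring

def test_score_links_closed_forms():
    assert score_links(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == 0.5
    v = np.array([2.0, 0.0])
    assert score_links(v, v) == pytest.approx(1 / (1 + np.exp(-4)), rel=1e-12)
    assert score_links(v, v) > 0.9
    u, w = np.array([1.0, -2.0]), np.array([0.3, 0.7])
    assert score_links(u, w) == score_links(w, u)
    with pytest.raises(ValueError, match="dimension"):
        score_links(np.ones(2), np.ones(3))


# ---------------------------------------------------------------- augmentation

def _stack_and_embeddings(rng, scale=1.0):
    hier, masks = hierarchy_with_masks(rng)
    emb = {n: rng.normal(scale=scale, size=8) for n in sorted(hier.nodes)}
    return hier, masks, emb


def test_augmentation_never_removes_and_respects_threshold(rng):
    hier, masks, emb = _stack_and_embeddings(rng, scale=1.5)
    aug, ledger = augment_masks(masks, hier, emb, threshold=0.9)
    for orig, new in zip(masks.pathway_masks, aug.pathway_masks):
        assert ((new - orig) >= 0).all()
    for entry in ledger:
        assert entry["score"] > 0.9


def test_augmentation_noop_when_scores_below_threshold(rng):
    hier, masks, emb = _stack_and_embeddings(rng, scale=0.01)  # scores ~0.5
    aug, ledger = augment_masks(masks, hier, emb, threshold=0.9)
    assert ledger == []
    for orig, new in zip(masks.pathway_masks, aug.pathway_masks):
        np.testing.assert_array_equal(orig, new)


def test_single_engineered_link_matches_exhaustive_scan(rng):
    hier, masks, emb = _stack_and_embeddings(rng, scale=0.01)
    # engineer exactly one adjacent-layer non-edge above threshold
    added = None
    for k in range(len(masks.pathway_masks)):
        lower = masks.node_index[f"pathway_{k + 1}"]
        upper = masks.node_index[f"pathway_{k + 2}"]
        m = masks.pathway_masks[k]
        for i, u in enumerate(lower):
            for j, v in enumerate(upper):
                if m[i, j] == 0:
                    added = (u, v)
                    break
            if added:
                break
        if added:
            break
    if added is None:
        pytest.skip("random hierarchy happened to be complete")
    u, v = added
    emb[u] = np.full(8, 2.0)
    emb[v] = np.full(8, 2.0)  # sigmoid(32) ~ 1
    aug, ledger = augment_masks(masks, hier, emb, threshold=0.9)
    # exhaustive scan oracle over all adjacent-layer non-edges
    expect = []
    for k in range(len(masks.pathway_masks)):
        lower = masks.node_index[f"pathway_{k + 1}"]
        upper = masks.node_index[f"pathway_{k + 2}"]
        m = masks.pathway_masks[k]
        for i, a in enumerate(lower):
            for j, b in enumerate(upper):
                s = 1 / (1 + np.exp(-emb[a] @ emb[b]))
                if m[i, j] == 0 and s > 0.9:
                    expect.append((a, b))
    assert [(e["source"], e["target"]) for e in ledger] == expect
    assert (u, v) in expect


def test_raising_threshold_adds_subset(rng):
    hier, masks, emb = _stack_and_embeddings(rng, scale=1.2)
    _, led_90 = augment_masks(masks, hier, emb, threshold=0.9)
    _, led_95 = augment_masks(masks, hier, emb, threshold=0.95)
    pairs90 = {(e["source"], e["target"]) for e in led_90}
    pairs95 = {(e["source"], e["target"]) for e in led_95}
    assert pairs95 <= pairs90


def test_augment_rejects_bad_threshold(rng):
    hier, masks, emb = _stack_and_embeddings(rng)
    for bad in (0.0, 1.0, -0.2, 1.5):
        with pytest.raises(ValueError, match="threshold"):
            augment_masks(masks, hier, emb, threshold=bad)
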