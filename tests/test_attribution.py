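"""Difference-from-reference attribution: Rescale rule, aggregation, export."""

import json

import numpy as np
import pytest

from pathlift.attribution import (aggregate_global, attribute_samples,
                                  deeplift_rescale, export_scores, rank_nodes,
                                  reference_forward)
from pathlift.network import forward, init_params

from conftest import chain_maskstack, hierarchy_with_masks


# ---------------------------------------------------------------- reference

def test_reference_zero_bias_network(tiny_stack):
    params = init_params(tiny_stack, seed=0)
    prob, cache = reference_forward(tiny_stack, params)
    for a in cache["as"][1:]:
        np.testing.assert_array_equal(a, 0.0)  # tanh(0) = 0 everywhere
    assert prob[0] == 0.5


def test_reference_with_biases_equals_forward_on_zero(small_model, rng):
    _, masks, params = small_model
    for b in params.layer_biases:
        b[:] = rng.normal(size=b.shape)
    params.head_b1[:] = rng.normal(size=params.head_b1.shape)
    params.head_b2 = 0.3
    prob, cache = reference_forward(masks, params)
    x0 = np.zeros((1, masks.input_mask.shape[0]))
    prob2, cache2 = forward(x0, masks, params, return_intermediates=True)
    np.testing.assert_array_equal(prob, prob2)
    for a, b_ in zip(cache["as"], cache2["as"]):
        np.testing.assert_array_equal(a, b_)


# ---------------------------------------------------------------- rescale

def test_zero_input_sample_gets_zero_contributions(small_model):
    _, masks, params = small_model
    c = deeplift_rescale(np.zeros(masks.input_mask.shape[0]), masks, params)
    for arr in c.values():
        np.testing.assert_array_equal(arr, 0.0)


def test_single_tanh_unit_scalar_rescale():
    """t = tanh(w x), w = 2, x = 1, zero reference: the input's contribution
    is tanh(2) - tanh(0) by the Rescale definition."""
    stack = chain_maskstack(n_pathway_layers=1)
    # collapse to: feature --w=2--> gene, then identity-ish head
    params = init_params(stack, seed=0)
    params.layer_weights[0][:] = 2.0   # feature -> gene: z = 2x
    params.layer_weights[1][:] = 1.0   # gene -> pathway_1
    params.head_w1[:] = 0.0
    params.head_w1[0, 0] = 1.0
    params.head_b1[:] = 0.0
    params.head_w2[:] = 0.0
    params.head_w2[0] = 1.0
    for b in params.layer_biases:
        b[:] = 0.0
    c = deeplift_rescale(np.array([1.0]), stack, params)
    _, cache = forward(np.array([[1.0]]), stack, params, return_intermediates=True)
    t = cache["logit"][0]
    # the single gene node carries the whole delta: C = t - t0 with t0 = 0
    np.testing.assert_allclose(c["gene"][0, 0], t, rtol=1e-10)
    # first nonlinearity alone: its delta-out is tanh(2) - tanh(0), the
    # hand-computed Rescale numerator for the w=2, x=1 scalar unit
    assert cache["as"][1][0, 0] == pytest.approx(np.tanh(2.0) - np.tanh(0.0),
                                                 rel=1e-12)
    # and the feature contribution equals the gene one (single path)
    np.testing.assert_allclose(c["feature"][0, 0], t, rtol=1e-10)


def test_summation_to_delta_on_random_models(rng):
    hier, masks = hierarchy_with_masks(rng)
    params = init_params(masks, seed=7)
    for b in params.layer_biases:
        b[:] = rng.normal(scale=0.3, size=b.shape)
    X = rng.normal(size=(25, masks.input_mask.shape[0]))
    ref = reference_forward(masks, params)
    c = deeplift_rescale(X, masks, params, reference=ref)
    _, cache = forward(X, masks, params, return_intermediates=True)
    d_logit = cache["logit"] - ref[1]["logit"]
    for name, arr in c.items():
        np.testing.assert_allclose(arr.sum(axis=1), d_logit, rtol=1e-5,
                                   err_msg=f"stratum {name}")


def test_linear_network_contributions_are_path_products(rng):
    """Identity activations: input i's contribution is x_i times the product
    of weights along all paths from i to the output."""
    hier, masks = hierarchy_with_masks(rng, widths=(2, 2, 1))
    params = init_params(masks, seed=2, activation="identity")
    for b in params.layer_biases:
        b[:] = rng.normal(size=b.shape)  # biases cancel in delta terms
    x = rng.normal(size=masks.input_mask.shape[0])
    c = deeplift_rescale(x, masks, params)
    # independent path-product oracle: chain of effective weight matrices
    W_eff = [m * w for m, w in zip(masks.masks, params.layer_weights)]
    chain = np.linalg.multi_dot(W_eff + [params.head_w1, params.head_w2[:, None]]) \
        if len(W_eff) > 1 else W_eff[0] @ params.head_w1 @ params.head_w2[:, None]
    np.testing.assert_allclose(c["feature"][0], x * chain.ravel(), rtol=1e-10)


def test_gradient_times_delta_mode_runs_but_differs(small_model, rng):
    _, masks, params = small_model
    x = rng.normal(size=(3, masks.input_mask.shape[0]))
    lit = deeplift_rescale(x, masks, params, mode="gradient_times_delta")
    res = deeplift_rescale(x, masks, params, mode="rescale")
    assert set(lit) == set(res)
    assert not np.allclose(lit["feature"], res["feature"])
    with pytest.raises(ValueError, match="unknown attribution mode"):
        deeplift_rescale(x, masks, params, mode="shapley")


# ---------------------------------------------------------------- aggregation

def test_aggregate_matches_bruteforce_sum(rng):
    per = {"gene": rng.normal(size=(3, 5))}
    out = aggregate_global(per)
    np.testing.assert_allclose(out["gene"]["sc"],
                               per["gene"][0] + per["gene"][1] + per["gene"][2])


def test_aggregate_single_sample_and_cancellation(rng):
    c = rng.normal(size=(1, 4))
    per = {"gene": np.vstack([c, -c])}
    assert np.allclose(aggregate_global(per, [0])["gene"]["sc"], c[0])
    assert np.allclose(aggregate_global(per)["gene"]["sc"], 0.0)
    with pytest.raises(ValueError, match="empty sample set"):
        aggregate_global(per, [])


def test_aggregation_is_additive_over_disjoint_sets(rng):
    per = {"gene": rng.normal(size=(10, 6))}
    s1, s2 = list(range(4)), list(range(4, 10))
    total = aggregate_global(per)["gene"]["sc"]
    parts = (aggregate_global(per, s1)["gene"]["sc"]
             + aggregate_global(per, s2)["gene"]["sc"])
    np.testing.assert_allclose(total, parts)


def test_per_class_sums_split_the_total(rng):
    per = {"gene": rng.normal(size=(8, 3))}
    labels = np.array([1, 0, 1, 0, 0, 1, 0, 0])
    out = aggregate_global(per, labels=labels)["gene"]
    np.testing.assert_allclose(out["sc"], out["sc_pos"] + out["sc_neg"])


# ---------------------------------------------------------------- ranking

def _table_with(scores, ids):
    from pathlift.attribution import ImportanceTable
    return ImportanceTable(per_sample={"gene": np.array([scores])},
                           global_scores={"gene": np.array(scores, dtype=float)},
                           node_index={"gene": ids}, sample_ids=["S0"],
                           reference_logit=0.0)


def test_rank_by_absolute_score():
    t = _table_with([3.0, -5.0, 0.0], ["a", "b", "c"])
    assert list(rank_nodes(t, "gene")["node"]) == ["b", "a", "c"]


def test_rank_ties_break_lexicographically():
    t = _table_with([1.0, -1.0, 1.0], ["z", "a", "m"])
    assert list(rank_nodes(t, "gene")["node"]) == ["a", "m", "z"]


def test_rank_unknown_layer_raises():
    t = _table_with([1.0], ["a"])
    with pytest.raises(KeyError, match="unknown layer"):
        rank_nodes(t, "protein")


# ---------------------------------------------------------------- export

def test_export_round_trips_scores_and_counts(tmp_path, small_model, rng):
    hier, masks, params = small_model
    X = rng.normal(size=(6, masks.input_mask.shape[0]))
    table = attribute_samples(X, masks, params)
    export_scores(table, masks, tmp_path)
    # bit-exact score round trip from the gene TSV
    lines = (tmp_path / "scores_gene.tsv").read_text().strip().split("\n")[1:]
    read_back = {ln.split("\t")[1]: float(ln.split("\t")[2]) for ln in lines}
    ids = table.node_index["gene"]
    for i, nid in enumerate(ids):
        assert read_back[nid] == table.global_scores["gene"][i]  # exact
    graph = json.loads((tmp_path / "importance_graph.json").read_text())
    n_strata_nodes = sum(len(table.node_index[s]) for s in masks.layer_names)
    assert len(graph["nodes"]) == n_strata_nodes
    assert len(graph["edges"]) == int(sum(m.sum() for m in masks.masks))
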