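"""Class tests on fully directed multi-rooted networks."""

import random

import pytest

from sdnet.core import GraphError, build_graph
from sdnet.rooted import (
    binary_resolution,
    is_forest_based_rooted,
    is_multi_rooted_network,
    is_orchard_rooted,
    is_tree_based_rooted,
    is_tree_child_rooted,
    search_hgt_labelling,
    tree_based_oracle,
    verify_hgt_labelling,
    verify_support_forest,
)
from sdnet.rooting import RootConfiguration, apply_root_configuration, enumerate_rootings

from conftest import random_network_stream


def rooting_at_u(fx):
    return apply_root_configuration(
        fx["F3"], RootConfiguration.of(vertices=["u"])
    ).network


def test_is_multi_rooted_network(fx):
    assert is_multi_rooted_network(rooting_at_u(fx))
    assert not is_multi_rooted_network(fx["F3"])  # has edges
    cyc = build_graph("abc", arcs=[("a", "b"), ("b", "c"), ("c", "a")], taxa=[])
    assert not is_multi_rooted_network(cyc)
    deg2 = build_graph("abc", arcs=[("a", "b"), ("b", "c")], taxa=[])
    assert not is_multi_rooted_network(deg2)  # b is a degree-2 non-root


def test_tree_child(fx):
    assert is_tree_child_rooted(rooting_at_u(fx))
    tree = build_graph("rab", arcs=[("r", "a"), ("r", "b")])
    assert is_tree_child_rooted(tree)
    # a vertex whose children are all reticulations
    bad = build_graph(
        ["s", "t", "r1", "r2", "a", "b"],
        arcs=[("s", "r1"), ("s", "r2"), ("t", "r1"), ("t", "r2"),
              ("r1", "a"), ("r2", "b")],
    )
    assert not is_tree_child_rooted(bad)


def test_tree_based_examples(fx):
    d = rooting_at_u(fx)
    ok, tree = is_tree_based_rooted(d, return_witness=True)
    assert ok and tree_based_oracle(d)
    # the witness spans all vertices and keeps every internal vertex busy
    tails = {t for (t, _) in tree}
    heads = {h for (_, h) in tree}
    assert tails | heads == d.vertices
    assert all(v in tails for v in d.vertices if v not in d.leaves())
    two_rooted = build_graph("pqxy", arcs=[("p", "x"), ("q", "y")], taxa="xy")
    assert not is_tree_based_rooted(two_rooted)


def test_tree_based_matching_equals_spanning_tree_oracle():
    for n in random_network_stream(41, 25):
        for r in enumerate_rootings(n):
            if len(r.network.vertices) <= 14:
                assert is_tree_based_rooted(r.network) == tree_based_oracle(r.network)


def test_orchard_rooted(fx):
    d = rooting_at_u(fx)
    ok, trace = is_orchard_rooted(d, return_trace=True)
    assert ok and trace
    cat = build_graph(
        ["r", "i", "a", "b", "c"],
        arcs=[("r", "a"), ("r", "i"), ("i", "b"), ("i", "c")],
    )
    assert is_orchard_rooted(cat)


def test_orchard_rooted_order_invariance():
    for n in random_network_stream(47, 15):
        for r in list(enumerate_rootings(n))[:3]:
            base = is_orchard_rooted(r.network)
            for seed in range(5):
                assert is_orchard_rooted(
                    r.network, rng=random.Random(seed)
                ) == base


def test_forest_based_witness_and_verifier(fx):
    d = rooting_at_u(fx)
    assert verify_support_forest(d, {("u", "v"), ("v", "b"), ("r", "c")})
    ok, witness = is_forest_based_rooted(d, return_witness=True)
    assert ok and verify_support_forest(d, witness)
    # a rooted tree is forest-based with all of its arcs
    tree = build_graph("rab", arcs=[("r", "a"), ("r", "b")])
    assert verify_support_forest(tree, tree.arcs)
    assert is_forest_based_rooted(tree)
    # a forest may not reuse a reticulation as two trees' junction
    assert not verify_support_forest(d, {("u", "r"), ("v", "r"), ("r", "c")})


def test_forest_based_witnesses_always_verify():
    for n in random_network_stream(53, 20):
        for r in list(enumerate_rootings(n, leaf_preserving=True))[:4]:
            ok, witness = is_forest_based_rooted(r.network, return_witness=True)
            if ok:
                assert verify_support_forest(r.network, witness)


def test_binary_resolution():
    star = build_graph("rabc", arcs=[("r", "a"), ("r", "b"), ("r", "c")])
    b = binary_resolution(star)
    assert len(b.vertices) == 5
    assert all(len(b.children(v)) in (0, 2) for v in b.vertices)
    # indegree-3 reticulation becomes a chain of indegree-2 ones
    g = build_graph(
        ["s", "p1", "p2", "p3", "r", "x", "a1", "a2", "a3"],
        arcs=[("s", "p1"), ("s", "p2"), ("s", "p3"), ("p1", "a1"), ("p2", "a2"),
              ("p3", "a3"), ("p1", "r"), ("p2", "r"), ("p3", "r"), ("r", "x")],
    )
    # s has outdegree 3 and r indegree 3
    b = binary_resolution(g)
    assert is_multi_rooted_network(b)
    for v in b.vertices:
        ins = len(b.parents(v))
        outs = len(b.children(v))
        assert ins <= 2 and (ins + outs) in (1, 2, 3)
    assert binary_resolution(b) == b  # already binary: unchanged


def test_hgt_labelling_verify():
    path = build_graph("abcz", arcs=[("a", "b"), ("b", "c"), ("b", "z")],
                       taxa=["c", "z"])
    assert verify_hgt_labelling(path, {"a": 0, "b": 1, "c": 2, "z": 2})
    assert not verify_hgt_labelling(path, {"a": 0, "b": 0, "c": 0, "z": 0})
    with pytest.raises(GraphError):
        verify_hgt_labelling(path, {"a": 0})


def test_hgt_search_on_f3_rooting(fx):
    d = binary_resolution(rooting_at_u(fx))
    lab = search_hgt_labelling(d)
    assert lab is not None and verify_hgt_labelling(d, lab)


def test_hgt_labelling_exists_iff_orchard():
    """For a rooted (single-root) binary-resolved network, an
    HGT-consistent labelling exists exactly when the network is
    orchard."""
    checked = 0
    for n in random_network_stream(61, 30, k_choices=(1,), max_vertices=11):
        for r in list(enumerate_rootings(n))[:4]:
            d = binary_resolution(r.network)
            if len(d.roots()) != 1:
                continue
            lab = search_hgt_labelling(d)
            assert (lab is not None) == is_orchard_rooted(d)
            if lab is not None:
                assert verify_hgt_labelling(d, lab)
            checked += 1
    assert checked >= 20
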