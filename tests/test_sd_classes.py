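"""Weak/strong tree-child, tree-based and forest-based deciders at the
(multi-)semi-directed level, and the path-collection machinery."""

import pytest

from sdnet.core import GraphError
from sdnet.rooted import is_forest_based_rooted, is_tree_based_rooted
from sdnet.rooting import RootConfiguration, apply_root_configuration, enumerate_rootings
from sdnet.sd_classes import (
    PathCollection,
    collection_to_rooting,
    cross_components,
    delta_plus,
    find_path_collection,
    hall_condition_oracle,
    is_strongly_forest_based,
    is_strongly_tree_based,
    is_strongly_tree_child,
    is_strongly_tree_child_brute,
    is_weakly_forest_based,
    is_weakly_tree_based,
    is_weakly_tree_child,
    is_weakly_tree_child_brute,
    is_weakly_tree_child_single_rooted,
    omnians,
    support_to_collection,
    verify_path_collection,
)
from sdnet.recognition import is_semi_directed

from conftest import random_network_stream


def test_omnians_and_delta_plus(fx):
    assert omnians(fx["F3"]) == set()
    assert omnians(fx["F7"]) == {"o"}
    assert delta_plus(fx["F7"], {"o"}) == {"r1", "r2"}
    assert delta_plus(fx["F7"], set()) == set()
    with pytest.raises(GraphError):
        delta_plus(fx["F7"], {"a"})


def test_tree_child_fixtures(fx):
    assert is_strongly_tree_child(fx["F3"])
    assert not is_strongly_tree_child(fx["F7"])
    assert is_strongly_tree_child(fx["fig7_N1"])
    assert is_weakly_tree_child(fx["F7"])
    assert is_weakly_tree_child(fx["F3"])
    assert not is_weakly_tree_child(fx["fig7_N3"])
    with pytest.raises(GraphError):
        is_strongly_tree_child(fx["F5"])


def test_tree_child_omnian_criteria_match_brute_force():
    for n in random_network_stream(71, 50):
        assert is_strongly_tree_child(n) == is_strongly_tree_child_brute(n)
        assert is_weakly_tree_child(n) == is_weakly_tree_child_brute(n)
        if is_semi_directed(n):
            assert is_weakly_tree_child(n) == is_weakly_tree_child_single_rooted(n)


def test_strongly_tree_based_fixtures(fx):
    assert is_strongly_tree_based(fx["F3"])
    ok, reason = is_strongly_tree_based(fx["F7"], return_reason=True)
    assert not ok and "semi-directed" in reason
    assert not is_strongly_tree_based(fx["fig8_N"])
    assert is_weakly_tree_based(fx["fig8_N"])


def test_hall_matching_equals_subset_oracle_and_rootings():
    for n in random_network_stream(83, 40):
        if not is_semi_directed(n):
            continue
        fast = is_strongly_tree_based(n)
        assert fast == hall_condition_oracle(n)
        assert fast == all(
            is_tree_based_rooted(r.network) for r in enumerate_rootings(n)
        )


def test_verify_path_collection_on_f3(fx):
    f3 = fx["F3"]
    p = PathCollection.of([("u", "v", "b"), ("r", "c"), ("a",)])
    assert verify_path_collection(f3, p, "P123")
    assert verify_path_collection(f3, p, "P1234")
    # dropping a vertex breaks P1
    p_bad = PathCollection.of([("u", "v", "b"), ("r", "c")])
    assert not verify_path_collection(f3, p_bad, "P123")
    # a path ending outside the taxon set breaks P2
    p_bad = PathCollection.of([("b", "v", "u"), ("r", "c"), ("a",)])
    assert not verify_path_collection(f3, p_bad, "P123")
    with pytest.raises(GraphError):
        verify_path_collection(f3, p, "P12345")


def test_fig15_collection(fx):
    n = fx["fig15_N"]
    coll = find_path_collection(n, "P123")
    assert coll is not None
    assert verify_path_collection(n, coll, "P123")
    assert len(cross_components(n, coll)) >= 1


def test_collection_to_rooting_f3(fx):
    f3 = fx["F3"]
    p = PathCollection.of([("u", "v", "b"), ("r", "c"), ("a",)])
    rooting = collection_to_rooting(f3, p)
    assert rooting.network.arcs == frozenset(
        {("u", "a"), ("u", "v"), ("u", "r"), ("v", "b"), ("v", "r"), ("r", "c")}
    )


def test_support_to_collection_round_trip(fx):
    d = apply_root_configuration(
        fx["F3"], RootConfiguration.of(vertices=["u"])
    ).network
    coll = support_to_collection(d, {("u", "v"), ("v", "b"), ("r", "c")})
    assert set(coll.paths) == {("a",), ("r", "c"), ("u", "v", "b")}


def test_forest_and_tree_based_fixtures(fx):
    assert is_weakly_forest_based(fx["F3"])
    assert is_weakly_tree_based(fx["F3"])
    assert is_strongly_forest_based(fx["F3"])
    assert is_weakly_tree_based(fx["fig13_N3"])
    assert not is_weakly_forest_based(fx["fig13_N3"])
    assert not is_weakly_tree_child(fx["fig13_N3"])
    assert is_weakly_forest_based(fx["fig13_N2"])
    assert is_weakly_tree_based(fx["fig13_N2"])
    assert not is_weakly_tree_child(fx["fig13_N2"])
    assert is_weakly_forest_based(fx["fig14_N"])
    assert not is_strongly_forest_based(fx["fig14_N"])


def test_path_collection_search_matches_rooting_enumeration():
    """Weak forest-basedness (some leaf-preserving rooting with a
    support forest) coincides with the existence of a path collection
    satisfying all four properties; similarly for tree-basedness with
    the first three."""
    for n in random_network_stream(97, 35):
        wfb = is_weakly_forest_based(n)
        p4 = find_path_collection(n, "P1234")
        assert wfb == (p4 is not None)
        if p4 is not None:
            rooting = collection_to_rooting(n, p4, "P1234")
            assert is_forest_based_rooted(rooting.network)
        if is_semi_directed(n):
            wtb = is_weakly_tree_based(n)
            p3 = find_path_collection(n, "P123")
            assert wtb == (p3 is not None)
            if p3 is not None:
                rooting = collection_to_rooting(n, p3, "P123")
                assert is_tree_based_rooted(rooting.network)


def test_support_forests_decompose_into_valid_collections():
    for n in random_network_stream(103, 25):
        for r in list(enumerate_rootings(n, leaf_preserving=True))[:3]:
            ok, witness = is_forest_based_rooted(r.network, return_witness=True)
            if not ok:
                continue
            coll = support_to_collection(r.network, witness)
            assert verify_path_collection(r.network, coll, "P123")
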