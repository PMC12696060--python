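"""Mixed-graph model: validation, degrees, roles, components, cycles,
subdivision/suppression and semi-deorientation."""

import random

import pytest

from sdnet.core import (
    GraphError,
    build_graph,
    cycle_sinks,
    degree_profile,
    edge_path_between,
    enumerate_cycles,
    find_semi_directed_cycle,
    is_pendant_subtree,
    is_semi_directed_cycle,
    semi_deorient,
    sink_components,
    source_components,
    subdivide,
    suppress,
    undirected_components,
    vertex_roles,
    wedge_path_exists,
)

from conftest import random_mixed_graph, random_rooted_stream


@pytest.mark.parametrize(
    "kwargs, message",
    [
        (dict(vertices="xy", edges=[("x", "x")]), "self-loop"),
        (dict(vertices="uv", arcs=[("u", "v"), ("v", "u")]), "antiparallel"),
        (dict(vertices="uv", edges=[("u", "v")], arcs=[("u", "v")]), "parallel"),
        (dict(vertices="u", edges=[("u", "w")]), "dangling"),
        (dict(vertices="uv", arcs=[("u", "v"), ("u", "v")]), "duplicate"),
        (dict(vertices="uv", taxa=["z"]), "taxa"),
    ],
)
def test_build_graph_rejects_malformed_input(kwargs, message):
    with pytest.raises(GraphError, match=message):
        build_graph(**kwargs)


def test_taxa_default_to_structural_leaves(fx):
    assert fx["F1"].taxa == frozenset("xy")
    assert fx["F3"].taxa == frozenset("abc")
    # F5's t-vertices have outdegree 1, hence are not leaves
    assert fx["F5"].leaves() == set()


def test_degree_profiles_on_f3(fx):
    f3 = fx["F3"]
    r = degree_profile(f3, "r")
    assert (r.total, r.indeg, r.outdeg, r.edgedeg) == (3, 2, 0, 1)
    u = degree_profile(f3, "u")
    assert (u.total, u.indeg, u.outdeg, u.edgedeg) == (3, 0, 1, 2)
    x = degree_profile(fx["F1"], "x")
    assert (x.total, x.indeg, x.outdeg, x.edgedeg) == (1, 0, 0, 1)
    with pytest.raises(GraphError):
        degree_profile(f3, "missing")


def test_degree_sum_identity_on_random_graphs():
    rng = random.Random(3)
    for _ in range(30):
        g = random_mixed_graph(rng, rng.randint(2, 9))
        for v in g.vertices:
            d = degree_profile(g, v)
            assert d.total == d.indeg + d.outdeg + d.edgedeg


def test_vertex_roles(fx):
    f3 = fx["F3"]
    assert vertex_roles(f3, "r") == {"reticulation"}
    assert vertex_roles(f3, "a") == {"leaf"}
    assert vertex_roles(fx["F7"], "o") == {"omnian"}
    iso = build_graph(["v", "w"], edges=[], arcs=[], taxa=[])
    assert "root" in vertex_roles(iso, "v")  # isolated vertices are roots


def test_components_and_pendant_subtrees(fx):
    f3 = fx["F3"]
    comps = {frozenset(c) for c in undirected_components(f3)}
    assert comps == {frozenset("auvb"), frozenset("rc")}
    assert [set(c) for c in source_components(f3)] == [set("abuv")]
    assert [set(c) for c in sink_components(f3)] == [set("cr")]
    assert is_pendant_subtree(f3, {"r", "c"})
    assert is_pendant_subtree(f3, {"c"})
    assert not is_pendant_subtree(fx["F5"], {"r1", "r2"})
    with pytest.raises(GraphError):
        is_pendant_subtree(f3, {"a", "b"})  # not edge-connected


def test_fig3_source_and_sink_components(fx):
    n = fx["fig3_N"]
    assert {frozenset(c) for c in source_components(n)} == {
        frozenset({"a", "b", "v1", "v3", "v4", "v7"}), frozenset({"e"})
    }
    assert {frozenset(c) for c in sink_components(n)} == {
        frozenset({"d", "r1"}), frozenset({"g", "r4"})
    }


def test_cycle_enumeration_and_sinks(fx):
    f3 = fx["F3"]
    assert enumerate_cycles(f3) == [("r", "u", "v")]
    assert enumerate_cycles(fx["F1"]) == []
    assert cycle_sinks(f3, ("u", "v", "r", "u")) == {"r"}
    tri = fx["F2"]
    assert cycle_sinks(tri, ("a", "b", "c", "a")) == set()
    fig3 = fx["fig3_N"]
    cyc = ("r2", "v3", "v4", "r3", "r4", "v7", "r2")
    assert any(set(c) == set(cyc[:-1]) for c in enumerate_cycles(fig3))
    assert cycle_sinks(fig3, cyc) == {"r2", "r4"}
    assert not is_semi_directed_cycle(fig3, cyc)


def test_semi_directed_cycle_witnesses(fx):
    assert find_semi_directed_cycle(fx["F3"]) is None
    w = find_semi_directed_cycle(fx["F6"])
    assert w is not None and is_semi_directed_cycle(fx["F6"], w)
    tri = fx["F2"]
    w = find_semi_directed_cycle(tri)
    assert w is not None and len(w) == 4  # the pure-edge triangle


def test_semi_directed_cycle_detector_matches_enumeration_oracle():
    """Component-contraction detection agrees with exhaustive cycle
    enumeration on random mixed graphs."""
    rng = random.Random(11)
    for _ in range(120):
        g = random_mixed_graph(rng, rng.randint(3, 9))
        fast = find_semi_directed_cycle(g)
        slow = any(
            is_semi_directed_cycle(g, c + (c[0],)) for c in enumerate_cycles(g)
        )
        assert (fast is not None) == slow
        if fast is not None:
            assert is_semi_directed_cycle(g, fast)


def test_edge_and_wedge_paths(fx):
    f3 = fx["F3"]
    assert edge_path_between(f3, "r", "c") == ("r", "c")
    assert edge_path_between(f3, "a", "c") is None
    assert edge_path_between(f3, "u", "u") == ("u",)
    assert wedge_path_exists(f3, "u", "u")
    assert wedge_path_exists(f3, "a", "c")
    fig3 = fx["fig3_N"]
    assert edge_path_between(fig3, "a", "v7") == ("a", "v1", "v3", "v4", "v7")
    # the published ∧-path endpoints of the reconstruction
    assert wedge_path_exists(fig3, "r1", "g")
    g1 = fx["fig5_G1"]
    assert not wedge_path_exists(g1, "v1", "v2")


def test_subdivide_edge_and_arc(fx):
    f1 = fx["F1"]
    g, w = subdivide(f1, frozenset(("x", "y")))
    assert g.has_edge("x", w) and g.has_edge(w, "y") and not g.has_edge("x", "y")
    g2, w2 = subdivide(g, frozenset(("x", w)))
    assert w2 != w
    f3 = fx["F3"]
    g3, w3 = subdivide(f3, ("u", "r"))
    d = degree_profile(g3, w3)
    assert (d.total, d.indeg, d.outdeg, d.edgedeg) == (2, 0, 1, 1)
    assert g3.has_edge("u", w3) and g3.has_arc(w3, "r")
    with pytest.raises(GraphError):
        subdivide(f3, ("r", "u"))


def test_suppress_cases_and_errors(fx):
    f1 = fx["F1"]
    g, w = subdivide(f1, frozenset(("x", "y")))
    assert suppress(g, w) == f1
    # arc-in + edge-out collapses to an edge
    g = build_graph("uwc", edges=[("w", "c")], arcs=[("u", "w")], taxa=[])
    out = suppress(g, "w")
    assert out.has_edge("u", "c") and not out.arcs
    # two incoming arcs are unsuppressible
    g = build_graph("uvw", arcs=[("u", "w"), ("v", "w")], taxa=[])
    with pytest.raises(GraphError, match="unsuppressible"):
        suppress(g, "w")
    # suppression producing a parallel pair is refused
    g = build_graph("abw", edges=[("a", "w"), ("w", "b"), ("a", "b")], taxa=[])
    with pytest.raises(GraphError, match="parallel"):
        suppress(g, "w")


def test_subdivide_then_suppress_is_identity():
    for d in random_rooted_stream(5, 10):
        n = semi_deorient(d)
        for elem in sorted(n.edges, key=sorted)[:2] + sorted(n.arcs)[:2]:
            g, w = subdivide(n, elem)
            assert suppress(g, w) == n


def test_semi_deorient_basics(fx):
    # cherry: the degree-2 root is suppressed
    d = build_graph("rxy", arcs=[("r", "x"), ("r", "y")])
    assert semi_deorient(d) == build_graph("xy", edges=[("x", "y")])
    # a root whose two arcs feed reticulations survives (unsuppressible)
    d = build_graph(
        ["s", "a", "b", "p1", "p2", "r1", "r2"],
        arcs=[("s", "r1"), ("s", "r2"), ("p1", "r1"), ("p2", "r2"),
              ("r1", "a"), ("r2", "b")],
        taxa=["a", "b"],
    )
    n = semi_deorient(d)
    assert "s" in n.vertices and n.has_arc("s", "r1") and n.has_arc("s", "r2")
    # rooted phylogenetic tree deorients to an unrooted tree
    d = build_graph("rpqabcd", arcs=[("r", "p"), ("r", "q"), ("p", "a"),
                                     ("p", "b"), ("q", "c"), ("q", "d")])
    n = semi_deorient(d)
    assert not n.arcs and "r" not in n.vertices and len(n.edges) == 5


def test_semi_deorient_leaves_no_orientable_arcs():
    for d in random_rooted_stream(7, 25):
        n = semi_deorient(d)
        indeg = {v: 0 for v in n.vertices}
        for (_, h) in n.arcs:
            indeg[h] += 1
        assert all(indeg[h] >= 2 for (_, h) in n.arcs)
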