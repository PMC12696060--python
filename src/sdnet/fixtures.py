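"""Named fixture graphs.

``F1``–``F7`` are small hand-built instances exercising specific
structural features (documented per fixture).  The ``fig*`` fixtures
are synthetic reconstructions of published illustrative examples: the
adjacency was *designed here* to satisfy the structural facts stated
about each example (source/sink components, cherries, class verdicts,
...), which the test suite asserts; they are not verbatim transcriptions
of any drawing.
"""

from __future__ import annotations

from functools import lru_cache

from .core import MixedGraph, build_graph

__all__ = ["fixtures"]


def _f1() -> MixedGraph:
    """Smallest network: a single edge on two taxa."""
    return build_graph("xy", edges=[("x", "y")])


def _f2() -> MixedGraph:
    """Triangle of edges: every vertex has degree 2 and the 3-cycle has
    no sink, so it is not multi-semi-directed."""
    return build_graph("abc", edges=[("a", "b"), ("b", "c"), ("c", "a")])


def _f3() -> MixedGraph:
    """A semi-directed network on {a, b, c}: one reticulation r fed from
    the chain a-u-v-b, with leaf c below r."""
    return build_graph(
        ["a", "b", "c", "u", "v", "r"],
        edges=[("a", "u"), ("u", "v"), ("v", "b"), ("r", "c")],
        arcs=[("u", "r"), ("v", "r")],
        taxa=["a", "b", "c"],
    )


def _f5() -> MixedGraph:
    """Two reticulations joined by an edge: violates the
    no-edge-path-between-reticulations condition."""
    return build_graph(
        ["t1", "t2", "t3", "t4", "r1", "r2"],
        edges=[("r1", "r2")],
        arcs=[("t1", "r1"), ("t2", "r1"), ("t3", "r2"), ("t4", "r2")],
        taxa=[],
    )


def _f6() -> MixedGraph:
    """Contains the semi-directed cycle (v1, v2, v3, v4, v1)."""
    return build_graph(
        ["v1", "v2", "v3", "v4", "w", "w2", "y", "z"],
        edges=[("v1", "v2"), ("v3", "v4"), ("v2", "y"), ("v4", "z")],
        arcs=[("v2", "v3"), ("w", "v3"), ("v4", "v1"), ("w2", "v1")],
        taxa=[],
    )


def _f7() -> MixedGraph:
    """A 2-semi-directed network with a single omnian o feeding two
    reticulations; weakly but not strongly tree-child."""
    return build_graph(
        ["o", "a", "b", "c", "p1", "r1", "r2", "x", "y"],
        edges=[("a", "o"), ("b", "p1"), ("p1", "c"), ("r1", "x"), ("r2", "y")],
        arcs=[("o", "r1"), ("o", "r2"), ("p1", "r1"), ("p1", "r2")],
        taxa=["a", "b", "c", "x", "y"],
    )


def _fig3() -> MixedGraph:
    """Synthetic reconstruction of a 2-semi-directed network with four
    reticulations, source components {a,b,v1,v3,v4,v7} and {e}, sink
    components {d,r1} and {g,r4}, cherry (a,b), and the cycle
    (r2,v3,v4,r3,r4,v7,r2) whose sinks are r2 and r4 but not r3."""
    return build_graph(
        ["a", "b", "d", "e", "g", "r1", "r2", "r3", "r4",
         "v1", "v2", "v3", "v4", "v5", "v7"],
        edges=[("a", "v1"), ("v1", "b"), ("v1", "v3"), ("v3", "v4"),
               ("v4", "v7"), ("v2", "v5"), ("v5", "r2"),
               ("d", "r1"), ("g", "r4")],
        arcs=[("v3", "r2"), ("v7", "r2"), ("e", "r2"),
              ("v4", "r3"), ("v2", "r3"),
              ("r3", "r4"), ("v7", "r4"),
              ("v2", "r1"), ("v5", "r1")],
        taxa=["a", "b", "d", "e", "g"],
    )


def _fig5_g1() -> MixedGraph:
    """Synthetic reconstruction: a connected 2-semi-directed network
    (two cherries feeding one reticulation) with no ∧-path between the
    cherry midpoints v1 and v2 — multi-semi-directed, not
    semi-directed."""
    return build_graph(
        ["a", "b", "c", "d", "v1", "v2", "r", "x"],
        edges=[("a", "v1"), ("v1", "b"), ("c", "v2"), ("v2", "d"), ("r", "x")],
        arcs=[("v1", "r"), ("v2", "r")],
        taxa=["a", "b", "c", "d", "x"],
    )


def _fig7_n1() -> MixedGraph:
    """Synthetic reconstruction: a semi-directed network on ten taxa
    with two reticulations and no omnians — strongly tree-child."""
    edges = [("v1", "v2"), ("v2", "v3"), ("v3", "v4"), ("v4", "v5"),
             ("v5", "v6"), ("v1", "x1"), ("v1", "x2"), ("v2", "x3"),
             ("v3", "x4"), ("v4", "x5"), ("v5", "x6"), ("v6", "x7"),
             ("v6", "x8"), ("r1", "x9"), ("r2", "x10")]
    arcs = [("v2", "r1"), ("v5", "r1"), ("v3", "r2"), ("v4", "r2")]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs,
                       taxa=[f"x{i}" for i in range(1, 11)])


def _fig7_n3() -> MixedGraph:
    """Synthetic reconstruction: a semi-directed network on eight taxa
    where the edge {r, o} joins a reticulation and an omnian — not
    weakly tree-child."""
    edges = [("u1", "u2"), ("u2", "u3"), ("u1", "x1"), ("u1", "x2"),
             ("u2", "x3"), ("u3", "x4"), ("u3", "x5"), ("u2", "x6"),
             ("o", "r"), ("r2", "x7"), ("r3", "x8")]
    arcs = [("u1", "r"), ("u3", "r"),
            ("o", "r2"), ("u2", "r2"), ("o", "r3"), ("u3", "r3")]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs,
                       taxa=[f"x{i}" for i in range(1, 9)])


def _fig8_n() -> MixedGraph:
    """Synthetic reconstruction: a semi-directed network that is weakly
    but not strongly tree-based.  Omnian o1 (one edge, two arcs) and the
    reticulation-omnians o2, o3 jointly feed only the two reticulations
    r1, r2, so Hall's condition fails; yet rooting at o1 orients its
    edge away and a tree-based rooting exists."""
    edges = [("u", "o1"), ("u", "x1"), ("u", "p2"), ("u", "p3"),
             ("p2", "x2"), ("p3", "x3"), ("r1", "a1"), ("r2", "a2")]
    arcs = [("p2", "o2"), ("p3", "o2"), ("p2", "o3"), ("p3", "o3"),
            ("o1", "r1"), ("o1", "r2"), ("o2", "r1"), ("o3", "r2")]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs, taxa=["x1", "x2", "x3", "a1", "a2"])


def _fig9_n() -> MixedGraph:
    """Synthetic reconstruction: a semi-directed network on six taxa
    that is weakly but not strongly orchard."""
    edges = [('a', 'v3'), ('b', 'r2'), ('c', 'v5'), ('d', 'v3'), ('e', 'r1'),
             ('f', 'v2'), ('v1', 'v2'), ('v1', 'v3'), ('v2', 'v4'),
             ('v4', 'v5'), ('v5', 'v6')]
    arcs = [('v1', 'r2'), ('v4', 'r1'), ('v6', 'r1'), ('v6', 'r2')]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs, taxa=['a', 'b', 'c', 'd', 'e', 'f'])


def _fig12_n() -> MixedGraph:
    """Synthetic reconstruction: a semi-directed network on five taxa
    that is weakly but not strongly orchard (a reticulation feeding a
    second reticulation)."""
    edges = [('a', 'v2'), ('b', 'r1'), ('c', 'v1'), ('d', 'v5'), ('e', 'v3'),
             ('v1', 'v3'), ('v1', 'v4'), ('v2', 'v4'), ('v2', 'v5')]
    arcs = [('r2', 'r1'), ('v3', 'r1'), ('v4', 'r2'), ('v5', 'r2')]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs, taxa=['a', 'b', 'c', 'd', 'e'])


def _fig13_n2() -> MixedGraph:
    """Synthetic reconstruction: weakly forest-based and weakly
    tree-based, but not weakly tree-child (two omnian-style feeders
    into two reticulations, one root)."""
    edges = [('a', 'r1'), ('b', 'v1'), ('c', 'v1'), ('d', 'r2'),
             ('v1', 'v3'), ('v2', 'v3'), ('v3', 'v4')]
    arcs = [('v2', 'r1'), ('v2', 'r2'), ('v4', 'r1'), ('v4', 'r2')]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs, taxa=['a', 'b', 'c', 'd'])


def _fig13_n3() -> MixedGraph:
    """Synthetic reconstruction: a three-taxon semi-directed network
    that is weakly tree-based but neither weakly tree-child nor weakly
    forest-based."""
    edges = [('a', 'v1'), ('b', 'r2'), ('c', 'v4'), ('r3', 'v1'),
             ('v1', 'v3'), ('v2', 'v4')]
    arcs = [('r1', 'r2'), ('v2', 'r1'), ('v2', 'r3'), ('v3', 'r1'),
            ('v3', 'r2'), ('v4', 'r3')]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs, taxa=['a', 'b', 'c'])


def _fig14_n() -> MixedGraph:
    """Synthetic reconstruction: a 2-semi-directed network that is
    weakly but not strongly forest-based."""
    edges = [('a', 'v1'), ('b', 'c'), ('d', 'r2'), ('e', 'v1'),
             ('v1', 'v2'), ('v2', 'v3')]
    arcs = [('r1', 'r2'), ('v2', 'r1'), ('v3', 'r1'), ('v3', 'r2')]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs, taxa=['a', 'b', 'c', 'd', 'e'])


def _fig15_n() -> MixedGraph:
    """Synthetic reconstruction: a seven-taxon semi-directed network
    carrying a path collection that satisfies the disjointness, taxon-
    endpoint and cross-component conditions (weakly forest-based)."""
    edges = [('a', 'v1'), ('b', 'v3'), ('c', 'v4'), ('d', 'v1'), ('e', 'v4'),
             ('f', 'r1'), ('g', 'v5'), ('v1', 'v2'), ('v2', 'v3'),
             ('v2', 'v6'), ('v3', 'v4'), ('v5', 'v6')]
    arcs = [('v5', 'r1'), ('v6', 'r1')]
    verts = {v for e in edges for v in e} | {v for a in arcs for v in a}
    return build_graph(verts, edges, arcs, taxa=['a', 'b', 'c', 'd', 'e', 'f', 'g'])


def _nice_rooting_gap() -> MixedGraph:
    """A 2-semi-directed network that is weakly orchard although its nice
    rooting with roots {T, p1} is not orchard.

    Reducing the cherry (x3, x5) suppresses T in the network (creating
    the edge {p2, x5} and, further down the line, new reticulated
    cherries) while T survives as a root in the rooting, whose
    reductions then dead-end.  Documents that "weakly orchard" cannot be
    decided by checking nice rootings alone.
    """
    return build_graph(
        ["T", "p1", "p2", "q1", "q2", "x1", "x3", "x5", "x6", "x7"],
        edges=[("T", "p2"), ("T", "x3"), ("T", "x5"),
               ("p1", "x6"), ("p1", "x7"), ("q1", "x1")],
        arcs=[("p1", "q2"), ("p2", "q1"), ("p2", "q2"), ("q2", "q1")],
        taxa=["x1", "x3", "x5", "x6", "x7"],
    )


@lru_cache(maxsize=1)
def fixtures() -> dict:
    """All named fixtures as a dict of MixedGraphs."""
    out = {
        "F1": _f1(),
        "F2": _f2(),
        "F3": _f3(),
        "F5": _f5(),
        "F6": _f6(),
        "F7": _f7(),
        "fig3_N": _fig3(),
        "fig5_G1": _fig5_g1(),
        "fig7_N1": _fig7_n1(),
        "fig7_N3": _fig7_n3(),
        "fig8_N": _fig8_n(),
        "fig9_N": _fig9_n(),
        "fig12_N": _fig12_n(),
        "fig13_N2": _fig13_n2(),
        "fig13_N3": _fig13_n3(),
        "fig14_N": _fig14_n(),
        "fig15_N": _fig15_n(),
        "nice_rooting_gap": _nice_rooting_gap(),
    }
    return out
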