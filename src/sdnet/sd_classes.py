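"""Tree-child, tree-based and forest-based membership for
(multi-)semi-directed networks, in the weak (some rooting) and strong
(every rooting) senses.

The fast characterizations all hinge on *omnians* — vertices with an
outgoing arc and at most one incident edge, i.e. vertices whose children
are all reticulations in every (or almost every) rooting:

* strongly tree-child  ⇔  no omnians;
* weakly tree-child    ⇔  at most one omnian per root, an incident edge
  everywhere, and no edge-path linking two omnians/reticulations;
* strongly tree-based  ⇔  Hall's condition on the bipartite graph
  pairing omnians with the reticulations they feed (semi-directed only:
  a tree-based rooting has a single root).

Weak tree-basedness and forest-basedness are characterized by
collections of vertex-disjoint semi-directed paths ending in taxa
(one per taxon), with conditions on the *cross components* formed by
edges joining different paths; such a collection can be rewound into an
explicit rooting and extracted back out of a support forest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import networkx as nx

from .core import (
    GraphError,
    MixedGraph,
    degree_profile,
    source_components,
    undirected_components,
)
from .recognition import is_multi_semi_directed, is_semi_directed, root_count
from .rooted import (
    is_forest_based_rooted,
    is_tree_based_rooted,
    is_tree_child_rooted,
    verify_support_forest,
)
from .rooting import Rooting, RootConfiguration, enumerate_rootings, is_rooting_of

__all__ = [
    "PathCollection",
    "omnians",
    "delta_plus",
    "is_strongly_tree_child",
    "is_weakly_tree_child",
    "is_strongly_tree_based",
    "verify_path_collection",
    "find_path_collection",
    "collection_to_rooting",
    "support_to_collection",
    "is_weakly_tree_based",
    "is_weakly_forest_based",
    "is_strongly_forest_based",
]


def omnians(network: MixedGraph) -> set:
    """Vertices with d⁺ ≥ 1 and dᵉ ≤ 1."""
    out = set()
    for v in network.vertices:
        d = degree_profile(network, v)
        if d.outdeg >= 1 and d.edgedeg <= 1:
            out.add(v)
    return out


def delta_plus(network: MixedGraph, subset: Iterable[str]) -> set:
    """Heads of arcs leaving *subset* (a set of omnians)."""
    s = set(subset)
    if not s <= omnians(network):
        raise GraphError("subset must consist of omnians")
    return {h for (t, h) in network.arcs if t in s}


def _require_msd(network: MixedGraph) -> None:
    if not is_multi_semi_directed(network):
        raise GraphError("not a multi-semi-directed network")


def is_strongly_tree_child(network: MixedGraph) -> bool:
    """Every rooting tree-child ⇔ the network has no omnians."""
    _require_msd(network)
    return not omnians(network)


def is_weakly_tree_child(network: MixedGraph) -> bool:
    """Some rooting tree-child ⇔ |O| ≤ k, every vertex meets an edge,
    and no undirected component holds two of the omnians/reticulations.

    For semi-directed inputs this reduces to: at most one omnian, and if
    there is one it has an incident edge and shares no undirected
    component with a reticulation.
    """
    _require_msd(network)
    omn = omnians(network)
    k = root_count(network)
    if len(omn) > k:
        return False
    if any(degree_profile(network, v).edgedeg == 0 for v in network.vertices):
        return False
    marked = omn | network.reticulations()
    return all(len(marked & comp) <= 1 for comp in undirected_components(network))


def is_weakly_tree_child_single_rooted(network: MixedGraph) -> bool:
    """The single-root simplification, tested to agree with the general
    criterion on semi-directed inputs."""
    if not is_semi_directed(network):
        raise GraphError("not a semi-directed network")
    omn = omnians(network)
    if len(omn) > 1:
        return False
    if not omn:
        return True
    o = next(iter(omn))
    if degree_profile(network, o).edgedeg < 1:
        return False
    comp = next(c for c in undirected_components(network) if o in c)
    return not (network.reticulations() & comp - {o})


def hall_condition_oracle(network: MixedGraph, max_omnians: int = 14) -> bool:
    """Subset-enumeration Hall oracle: |δ⁺(S)| ≥ |S| for all S ⊆ O."""
    omn = sorted(omnians(network))
    if len(omn) > max_omnians:
        raise GraphError("too many omnians for subset enumeration")
    for r in range(1, len(omn) + 1):
        for s in itertools.combinations(omn, r):
            if len(delta_plus(network, s)) < len(s):
                return False
    return True


def is_strongly_tree_based(network: MixedGraph, return_reason: bool = False):
    """Every rooting tree-based; demands a semi-directed input (a
    tree-based network has one root), so k ≥ 2 inputs are False with
    reason.  Decided by maximum matching in the omnian/reticulation
    bipartite graph (Hall's condition)."""
    _require_msd(network)
    if len(source_components(network)) >= 2:
        reason = "strongly tree-based implies semi-directed (single root)"
        return (False, reason) if return_reason else False
    omn = omnians(network)
    rets = network.reticulations()
    b = nx.Graph()
    b.add_nodes_from(("O", o) for o in omn)
    b.add_nodes_from(("R", r) for r in rets)
    for o in omn:
        for h in network.children(o):
            b.add_edge(("O", o), ("R", h))
    if omn:
        matching = nx.bipartite.maximum_matching(b, top_nodes=[("O", o) for o in omn])
        ok = all(("O", o) in matching for o in omn)
    else:
        ok = True
    return (ok, None) if return_reason else ok


# -- path collections ------------------------------------------------------


@dataclass(frozen=True)
class PathCollection:
    """A collection of vertex-disjoint semi-directed paths, one ending at
    each taxon.  The *handy vertex* of a path is its first vertex."""

    paths: tuple  # of tuples of vertex labels

    @classmethod
    def of(cls, paths: Iterable[Sequence[str]]) -> "PathCollection":
        return cls(tuple(sorted(tuple(p) for p in paths)))

    def __iter__(self):
        return iter(self.paths)

    def handy_vertices(self) -> set:
        return {p[0] for p in self.paths}

    def path_of(self) -> dict:
        out = {}
        for i, p in enumerate(self.paths):
            for v in p:
                out[v] = i
        return out


def _is_semi_directed_path(network: MixedGraph, path: Sequence[str]) -> bool:
    if len(set(path)) != len(path):
        return False
    return all(
        network.has_arc(path[i], path[i + 1]) or network.has_edge(path[i], path[i + 1])
        for i in range(len(path) - 1)
    )


def cross_components(network: MixedGraph, collection: PathCollection) -> list:
    """Maximal connected subgraphs made of edges joining different paths."""
    path_of = collection.path_of()
    g = nx.Graph()
    for e in network.edges:
        u, v = tuple(e)
        if u in path_of and v in path_of and path_of[u] != path_of[v]:
            g.add_edge(u, v)
    return [frozenset(c) for c in nx.connected_components(g)]


def verify_path_collection(network: MixedGraph, collection: PathCollection,
                           level: str = "P123") -> bool:
    """Check Properties P1–P3 (level="P123") or P1–P4 (level="P1234").

    P1: every vertex on exactly one path.  P2: each path is trivial on a
    taxon, or runs from a non-taxon vertex to a taxon.  P3: every cross
    component has at most one non-handy vertex.  P4: any two vertices of
    the same path that are adjacent in the network are consecutive on
    the path (the support arcs of the induced forest are exactly the
    path steps, so this is the different-trees condition for the rest).
    """
    if level not in ("P123", "P1234"):
        raise GraphError(f"unknown level {level!r}")
    taxa = set(network.taxa)
    counts = {}
    for p in collection:
        if not p or not _is_semi_directed_path(network, p):
            raise GraphError(f"malformed path {p}")
        for v in p:
            counts[v] = counts.get(v, 0) + 1
    if set(counts) != set(network.vertices) or any(c != 1 for c in counts.values()):
        return False  # P1
    for p in collection:
        if len(p) == 1:
            if p[0] not in taxa:
                return False  # P2
        elif p[0] in taxa or p[-1] not in taxa:
            return False  # P2
    handy = collection.handy_vertices()
    for comp in cross_components(network, collection):
        if len([v for v in comp if v not in handy]) > 1:
            return False  # P3
    if level == "P1234":
        path_of = collection.path_of()
        pos = {}
        for p in collection:
            for i, v in enumerate(p):
                pos[v] = i
        for u, v in [tuple(e) for e in network.edges] + [a for a in network.arcs]:
            if path_of[u] == path_of[v] and abs(pos[u] - pos[v]) != 1:
                return False  # P4
    return True


def find_path_collection(network: MixedGraph, level: str = "P123",
                         max_vertices: int = 16) -> Optional[PathCollection]:
    """Backtracking search for a path collection satisfying P1–P3 or
    P1–P4.  Desk scale; guarded by a vertex limit.

    A collection is encoded as a successor choice: each non-taxon vertex
    picks the next vertex on its path (via an edge or an outgoing arc),
    injectively, so that every chain ends at a distinct taxon.
    """
    _require_msd(network)
    if len(network.vertices) > max_vertices:
        raise GraphError("graph too large for path-collection search")
    taxa = set(network.taxa)
    non_taxa = sorted(v for v in network.vertices if v not in taxa)
    succ_opts = {
        v: sorted(network.edge_neighbors(v) | network.children(v)) for v in non_taxa
    }
    if any(not succ_opts[v] for v in non_taxa):
        return None

    def chain_end(assign: dict, s: str, stop: str):
        """Follow assigned successors from s; return the end, or None if
        the walk reaches *stop* (which would close a cycle)."""
        w = s
        while True:
            if w == stop:
                return None
            if w not in assign:
                return w
            w = assign[w]

    def build(assign: dict) -> Optional[PathCollection]:
        used_succ = set(assign.values())
        paths = []
        covered = set()
        for s in non_taxa:
            if s in used_succ:
                continue
            p = [s]
            while p[-1] in assign:
                p.append(assign[p[-1]])
            if p[-1] not in taxa:
                return None
            paths.append(tuple(p))
            covered |= set(p)
        for x in sorted(taxa & network.vertices):
            if x not in covered:
                paths.append((x,))
                covered.add(x)
        if covered != set(network.vertices):
            return None
        return PathCollection.of(paths)

    best: List[Optional[PathCollection]] = [None]

    def rec(i: int, assign: dict, used: set) -> bool:
        if i == len(non_taxa):
            coll = build(assign)
            if coll is not None and verify_path_collection(network, coll, level):
                best[0] = coll
                return True
            return False
        v = non_taxa[i]
        for s in succ_opts[v]:
            if s in used or chain_end(assign, s, v) is None:
                continue
            assign[v] = s
            used.add(s)
            if rec(i + 1, assign, used):
                return True
            del assign[v]
            used.remove(s)
        return False

    rec(0, {}, set())
    return best[0]


def collection_to_rooting(network: MixedGraph, collection: PathCollection,
                          level: str = "P123") -> Rooting:
    """Rewind a path collection into a rooting: orient each path towards
    its taxon, orient each cross component away from its unique
    non-handy vertex (falling back to the minimum-label non-leaf vertex,
    or to a fresh root subdividing a leaf-leaf edge in the degenerate
    all-leaf case), and keep all other arcs of the network."""
    if not verify_path_collection(network, collection, level):
        raise GraphError(f"collection fails {level}")
    oriented = set(network.arcs)
    directed_edges = {}
    for p in collection:
        for i in range(len(p) - 1):
            u, v = p[i], p[i + 1]
            if network.has_edge(u, v):
                directed_edges[frozenset((u, v))] = (u, v)
    handy = collection.handy_vertices()
    g_work = network
    submap = {}
    leaves = network.leaves()
    for comp in cross_components(network, collection):
        non_handy = sorted(v for v in comp if v not in handy)
        comp_edges = [e for e in network.edges if e <= comp
                      and frozenset(e) not in directed_edges]
        if non_handy:
            centre = non_handy[0]
        else:
            non_leaf = sorted(v for v in comp if v not in leaves)
            if non_leaf:
                centre = non_leaf[0]
            else:
                # all-leaf cross component: a single taxon-taxon edge;
                # root a fresh vertex subdividing it
                e = comp_edges[0]
                from .core import subdivide

                g_work, w = subdivide(g_work, e)
                submap[w] = frozenset(e)
                u, v = tuple(e)
                directed_edges[frozenset((u, w))] = (w, u)
                directed_edges[frozenset((w, v))] = (w, v)
                continue
        # BFS inside the cross component, away from the centre
        adj = {}
        for e in comp_edges:
            u, v = tuple(e)
            adj.setdefault(u, set()).add(v)
            adj.setdefault(v, set()).add(u)
        from collections import deque

        seenc = {centre}
        q = deque([centre])
        while q:
            x = q.popleft()
            for y in sorted(adj.get(x, ())):
                if y not in seenc:
                    seenc.add(y)
                    directed_edges[frozenset((x, y))] = (x, y)
                    q.append(y)
    missing = [e for e in g_work.edges if frozenset(e) not in directed_edges]
    if missing:
        raise GraphError(f"edges left unoriented: {sorted(map(sorted, missing))}")
    directed = g_work.replace(
        edges=frozenset(),
        arcs=frozenset(oriented) | frozenset(directed_edges.values()),
    )
    if not is_rooting_of(directed, network):
        raise GraphError("collection does not induce a rooting")
    cfg = RootConfiguration.of(
        vertices=[r for r in directed.roots() if r in network.vertices],
        edges=[submap[r] for r in directed.roots() if r in submap],
    )
    return Rooting(directed, network, cfg, submap)


def support_to_collection(rooted: MixedGraph, forest) -> PathCollection:
    """Decompose a support forest into the corresponding semi-directed
    paths of the deoriented network: delete all but one outgoing arc per
    branching vertex, then read off the maximal directed paths.

    Raises if the thinned forest still branches (an in-branching support
    forest does not decompose into paths)."""
    if not verify_support_forest(rooted, forest):
        raise GraphError("not a support forest")
    fset = {tuple(a) for a in forest}
    out_of = {}
    for (t, h) in sorted(fset):
        out_of.setdefault(t, []).append(h)
    succ = {t: hs[0] for t, hs in out_of.items()}
    indeg = {}
    for t, h in succ.items():
        indeg[h] = indeg.get(h, 0) + 1
    if any(c > 1 for c in indeg.values()):
        raise GraphError("support forest does not decompose into paths")
    starts = [v for v in rooted.vertices if indeg.get(v, 0) == 0]
    paths = []
    for s in sorted(starts):
        p = [s]
        while p[-1] in succ:
            p.append(succ[p[-1]])
        paths.append(tuple(p))
    return PathCollection.of(paths)


# -- weak / strong deciders over rootings ----------------------------------


def is_weakly_tree_based(network: MixedGraph) -> bool:
    """Some rooting tree-based.  Multi-rooted inputs are False (a
    tree-based network has a single root)."""
    _require_msd(network)
    if len(source_components(network)) >= 2:
        return False
    return any(is_tree_based_rooted(r.network) for r in enumerate_rootings(network))


def is_weakly_forest_based(network: MixedGraph) -> bool:
    """Some rooting with leaf set X is forest-based."""
    _require_msd(network)
    return any(
        is_forest_based_rooted(r.network)
        for r in enumerate_rootings(network, leaf_preserving=True)
    )


def is_strongly_forest_based(network: MixedGraph) -> bool:
    """Every rooting with leaf set X is forest-based."""
    _require_msd(network)
    rootings = list(enumerate_rootings(network, leaf_preserving=True))
    if not rootings:
        return False
    return all(is_forest_based_rooted(r.network) for r in rootings)


def is_strongly_tree_child_brute(network: MixedGraph) -> bool:
    _require_msd(network)
    return all(is_tree_child_rooted(r.network) for r in enumerate_rootings(network))


def is_weakly_tree_child_brute(network: MixedGraph) -> bool:
    _require_msd(network)
    return any(is_tree_child_rooted(r.network) for r in enumerate_rootings(network))
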