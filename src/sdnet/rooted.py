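"""Class tests on multi-rooted (fully directed) networks.

A multi-rooted network is a mixed graph with no edges, no directed
cycles, no degree-2 non-root vertices, and ``d⁻(v) ∈ {0, 1, d(v)−1}``
everywhere.  This module decides membership of such networks in the
tree-child, tree-based, orchard and forest-based classes, provides the
binary resolution used for HGT-consistent labellings, and ships the
exhaustive oracles the fast deciders are validated against.

Tree-based recognition reduces to a bipartite matching between the
network's omnian-like vertices (non-leaves all of whose children are
reticulations) and its reticulations; forest-based recognition is an
exact backtracking search over support forests (the problem carries no
known polynomial algorithm, so the search is guarded by a size limit).
"""

from __future__ import annotations

import itertools
from typing import Iterable, Optional

import networkx as nx

from .core import (
    GraphError,
    MixedGraph,
    degree_profile,
    suppress,
)

__all__ = [
    "is_multi_rooted_network",
    "directed_roots",
    "directed_leaves",
    "is_tree_child_rooted",
    "is_tree_based_rooted",
    "tree_based_oracle",
    "is_orchard_rooted",
    "rooted_cherries",
    "rooted_reticulated_cherries",
    "reduce_rooted_pair",
    "is_forest_based_rooted",
    "verify_support_forest",
    "binary_resolution",
    "verify_hgt_labelling",
    "search_hgt_labelling",
]


def _has_directed_cycle(network: MixedGraph) -> bool:
    g = nx.DiGraph()
    g.add_nodes_from(network.vertices)
    g.add_edges_from(network.arcs)
    return not nx.is_directed_acyclic_graph(g)


def is_multi_rooted_network(network: MixedGraph) -> bool:
    """E = ∅, acyclic, no degree-2 non-roots, d⁻ ∈ {0, 1, d−1}."""
    if network.edges:
        return False
    for v in network.vertices:
        d = degree_profile(network, v)
        if d.indeg not in (0, 1, d.total - 1):
            return False
        if d.total == 2 and d.outdeg != d.total:
            return False
    return not _has_directed_cycle(network)


def directed_roots(network: MixedGraph) -> set:
    return network.roots()


def directed_leaves(network: MixedGraph) -> set:
    return network.leaves()


def _check_network(network: MixedGraph) -> None:
    if not is_multi_rooted_network(network):
        raise GraphError("not a multi-rooted network")


def is_tree_child_rooted(network: MixedGraph) -> bool:
    """Every non-leaf vertex has at least one non-reticulation child.

    Isolated vertices (d = 0) are exempt: they are terminal components
    with no evolution to witness, mirroring how reductions set aside
    isolated taxa.
    """
    _check_network(network)
    rets = network.reticulations()
    leaves = network.leaves()
    for v in network.vertices:
        if v in leaves or degree_profile(network, v).total == 0:
            continue
        if all(c in rets for c in network.children(v)):
            return False
    return True


def _rooted_omnians(network: MixedGraph) -> set:
    """Non-leaf vertices, all of whose children are reticulations (and
    that have at least one child)."""
    rets = network.reticulations()
    leaves = network.leaves()
    out = set()
    for v in network.vertices:
        if v in leaves:
            continue
        kids = network.children(v)
        if kids and all(c in rets for c in kids):
            out.add(v)
    return out


def is_tree_based_rooted(network: MixedGraph, return_witness: bool = False):
    """Tree-based: the network has a rooted spanning tree with its own
    leaf set.  False outright for ≥ 2 roots (a spanning tree has one).

    Decided by maximum bipartite matching: each vertex whose children are
    all reticulations must donate one of its out-arcs to the spanning
    tree, and each reticulation can absorb at most one, so a matching
    covering all such vertices is necessary and sufficient.  With
    ``return_witness`` a witness spanning tree (arc set) is returned as
    second element when tree-based.
    """
    _check_network(network)
    if len(directed_roots(network)) != 1:
        return (False, None) if return_witness else False
    omn = _rooted_omnians(network)
    rets = network.reticulations()
    b = nx.Graph()
    b.add_nodes_from(("O", o) for o in omn)
    b.add_nodes_from(("R", r) for r in rets)
    for o in omn:
        for r in network.children(o):
            b.add_edge(("O", o), ("R", r))
    if omn:
        matching = nx.bipartite.maximum_matching(b, top_nodes=[("O", o) for o in omn])
    else:
        matching = {}
    covered = {o for o in omn if ("O", o) in matching}
    ok = covered == omn
    if not return_witness:
        return ok
    if not ok:
        return False, None
    tree = set()
    chosen_in = {}
    for o in omn:
        r = matching[("O", o)][1]
        tree.add((o, r))
        chosen_in[r] = o
    for r in rets:
        if r not in chosen_in:
            p = min(network.parents(r))
            tree.add((p, r))
    for (t, h) in network.arcs:
        if h not in rets:
            tree.add((t, h))
    return True, frozenset(tree)


def tree_based_oracle(network: MixedGraph, max_vertices: int = 16) -> bool:
    """Exhaustive spanning-tree search: choose one incoming arc per
    reticulation; the network is tree-based iff some choice leaves every
    internal vertex with an outgoing arc."""
    _check_network(network)
    if len(network.vertices) > max_vertices:
        raise GraphError("graph too large for spanning-tree oracle")
    if len(directed_roots(network)) != 1:
        return False
    rets = sorted(network.reticulations())
    leaves = network.leaves()
    base = [(t, h) for (t, h) in network.arcs if h not in set(rets)]
    choices = [sorted((p, r) for p in network.parents(r)) for r in rets]
    for combo in itertools.product(*choices):
        arcs = base + list(combo)
        outdeg = {v: 0 for v in network.vertices}
        for (t, _) in arcs:
            outdeg[t] += 1
        if all(outdeg[v] >= 1 for v in network.vertices if v not in leaves):
            return True
    return False


# -- orchard (rooted) ------------------------------------------------------


def rooted_cherries(network: MixedGraph) -> list:
    """Ordered leaf pairs (x, y) with a common parent (length-2 arc path)."""
    leaves = network.leaves()
    out = []
    for x in sorted(leaves):
        for p in network.parents(x):
            for y in sorted(network.children(p)):
                if y != x and y in leaves:
                    out.append((x, y))
    return sorted(set(out))


def rooted_reticulated_cherries(network: MixedGraph) -> list:
    """Ordered leaf pairs (x, y): y a reticulation leaf, length-3 path
    x ← p(x) → r → y with r the reticulation above y."""
    leaves = network.leaves()
    rets = network.reticulations()
    out = []
    for y in sorted(leaves):
        for r in network.parents(y):
            if r not in rets:
                continue
            for p in network.parents(r):
                for x in network.children(p):
                    if x != y and x in leaves and x not in rets:
                        out.append((x, y))
    return sorted(set(out))


def _suppress_if_possible(graph: MixedGraph, candidates: Iterable[str]) -> MixedGraph:
    """Suppress candidates that became suppressible degree-2 non-roots,
    cascading until stable."""
    pending = set(candidates)
    while pending:
        v = min(pending)
        pending.remove(v)
        if v not in graph.vertices:
            continue
        d = degree_profile(graph, v)
        if d.total != 2 or d.outdeg == d.total or d.indeg == 2:
            continue
        neigh = graph.neighbors(v)
        graph = suppress(graph, v)
        pending |= neigh
    return graph


def reduce_rooted_pair(network: MixedGraph, pair) -> MixedGraph:
    """Reduce a cherry (delete x, suppress) or reticulated cherry
    (delete the arc p(x) → r, suppress) in a multi-rooted network."""
    x, y = pair
    if pair in rooted_cherries(network):
        px = network.parents(x)
        g = network.replace(
            vertices=network.vertices - {x},
            arcs=frozenset(a for a in network.arcs if x not in a),
            taxa=network.taxa - {x},
        )
        return _suppress_if_possible(g, px)
    if pair in rooted_reticulated_cherries(network):
        rets = network.reticulations()
        for r in sorted(network.parents(y)):
            if r in rets:
                for p in sorted(network.parents(r)):
                    if x in network.children(p):
                        g = network.replace(arcs=network.arcs - {(p, r)})
                        return _suppress_if_possible(g, {p, r})
    raise GraphError(f"{pair} is not a reducible pair")


def _is_arc_union(network: MixedGraph) -> bool:
    """Every connected component is a single arc."""
    if network.edges:
        return False
    deg = {v: degree_profile(network, v) for v in network.vertices}
    if any(d.total != 1 for d in deg.values()):
        return False
    return True


def is_orchard_rooted(network: MixedGraph, return_trace: bool = False, rng=None):
    """Orchard: reducible to a disjoint union of arcs by cherry /
    reticulated-cherry reductions.

    Reduces the lexicographically first available pair at each step
    (order-independence of the verdict is a known property of rooted
    cherry reductions); an optional ``rng`` (random.Random) picks pairs
    at random instead, for order-invariance tests.  With ``return_trace``
    the pair sequence is returned as second element.
    """
    _check_network(network)
    g = network
    trace = []
    while True:
        if _is_arc_union(g):
            return (True, trace) if return_trace else True
        pairs = sorted(set(rooted_cherries(g)) | set(rooted_reticulated_cherries(g)))
        if not pairs:
            return (False, trace) if return_trace else False
        pick = rng.choice(pairs) if rng is not None else pairs[0]
        g = reduce_rooted_pair(g, pick)
        trace.append(pick)


# -- forest-based ----------------------------------------------------------


def verify_support_forest(network: MixedGraph, forest: Iterable) -> bool:
    """Check that *forest* (a set of arcs of the network) is a support
    forest: a vertex-spanning union of rooted trees (in-degree at most
    one and no cycles), every non-taxon vertex keeps an outgoing arc (so
    the forest's leaf set — its outdegree-0 vertices, single-vertex
    trees included — is the taxon set), and every arc outside the forest
    joins two different trees."""
    fset = frozenset(tuple(a) for a in forest)
    if not fset <= network.arcs:
        return False
    g = nx.Graph()
    g.add_nodes_from(network.vertices)
    g.add_edges_from(fset)
    if g.number_of_edges() != len(fset):  # duplicate undirected pair
        return False
    try:
        nx.find_cycle(g)
        return False
    except nx.NetworkXNoCycle:
        pass
    indeg = {v: 0 for v in network.vertices}
    outdeg = {v: 0 for v in network.vertices}
    for (t, h) in fset:
        outdeg[t] += 1
        indeg[h] += 1
    if any(c > 1 for c in indeg.values()):  # components must be rooted trees
        return False
    leaves_f = {v for v in network.vertices if outdeg[v] == 0}
    if leaves_f != set(network.taxa):
        return False
    comp_of = {}
    for i, comp in enumerate(nx.connected_components(g)):
        for v in comp:
            comp_of[v] = i
    return all(comp_of[t] != comp_of[h] for (t, h) in network.arcs - fset)


def is_forest_based_rooted(network: MixedGraph, return_witness: bool = False,
                           max_vertices: int = 24):
    """Forest-based: a spanning union of rooted trees with leaf set X
    whose non-forest arcs join different trees exists.

    Exact backtracking over choice functions: one outgoing arc per
    non-taxon vertex with pairwise distinct heads.  Any support forest
    can be thinned to this path-shaped form by deleting surplus outgoing
    arcs (which only refines the trees, preserving every condition), so
    the restriction loses nothing.
    """
    _check_network(network)
    if len(network.vertices) > max_vertices:
        raise GraphError("graph too large for forest-based search")
    non_taxa = sorted(v for v in network.vertices if v not in network.taxa)
    out_choices = [sorted((v, c) for c in network.children(v)) for v in non_taxa]
    if any(not c for c in out_choices):
        return (False, None) if return_witness else False

    witness = None
    for combo in itertools.product(*out_choices):
        heads = [h for (_, h) in combo]
        if len(set(heads)) != len(heads):
            continue
        if verify_support_forest(network, combo):
            witness = frozenset(combo)
            break
    ok = witness is not None
    if return_witness:
        return ok, witness
    return ok


# -- binary resolution and HGT-consistent labellings -----------------------


def binary_resolution(network: MixedGraph) -> MixedGraph:
    """Replace out-stars of outdegree ≥ 3 by rooted binary caterpillars
    and in-stars of indegree ≥ 3 by reversed caterpillars.

    Children/parents are attached in label-sorted order; fresh internal
    vertices are named ``v^o0``, ``v^i0``, ... after the star centre, so
    the result is deterministic.
    """
    _check_network(network)
    g = network
    for v in sorted(network.vertices):
        kids = sorted(g.children(v))
        if len(kids) >= 3:
            arcs = set(g.arcs) - {(v, c) for c in kids}
            verts = set(g.vertices)
            hub = v
            for i, c in enumerate(kids[:-2]):
                nxt = f"{v}^o{i}"
                verts.add(nxt)
                arcs |= {(hub, c), (hub, nxt)}
                hub = nxt
            arcs |= {(hub, kids[-2]), (hub, kids[-1])}
            g = g.replace(vertices=frozenset(verts), arcs=frozenset(arcs))
    for v in sorted(network.vertices):
        pars = sorted(g.parents(v))
        if len(pars) >= 3:
            arcs = set(g.arcs) - {(p, v) for p in pars}
            verts = set(g.vertices)
            hub = v
            for i, p in enumerate(pars[:-2]):
                nxt = f"{v}^i{i}"
                verts.add(nxt)
                arcs |= {(p, hub), (nxt, hub)}
                hub = nxt
            arcs |= {(pars[-2], hub), (pars[-1], hub)}
            g = g.replace(vertices=frozenset(verts), arcs=frozenset(arcs))
    return g


def verify_hgt_labelling(network: MixedGraph, labelling: dict) -> bool:
    """Check an HGT-consistent labelling of a binary multi-rooted network:
    weakly increasing along arcs, strictly into non-reticulations, and
    exactly one equal-label parent per reticulation.

    Additionally, every non-leaf vertex must keep at least one child
    with a strictly larger label: equal-label arcs model instantaneous
    lateral transfers, and the donating lineage has to continue in the
    underlying tree (deleting all equal-label arcs must leave a
    spanning forest with the same leaf set).  Without this, equal-label
    chains through consecutive reticulations, or a vertex donating to
    both of its children at once, admit labellings on networks that no
    cherry sequence can dissolve.
    """
    if set(labelling) != set(network.vertices):
        raise GraphError("labelling must be total on the vertex set")
    rets = network.reticulations()
    for (u, v) in network.arcs:
        if labelling[u] > labelling[v]:
            return False
        if v not in rets and labelling[u] >= labelling[v]:
            return False
    for r in rets:
        equal = [p for p in network.parents(r) if labelling[p] == labelling[r]]
        if len(equal) != 1:
            return False
    leaves = network.leaves()
    for v in network.vertices:
        if v in leaves or not network.children(v):
            continue
        if all(labelling[v] >= labelling[w] for w in network.children(v)):
            return False
    return True


def search_hgt_labelling(network: MixedGraph) -> Optional[dict]:
    """Find an HGT-consistent labelling of a binary multi-rooted network,
    or None.

    For each reticulation the equal-label parent is a free choice; once
    chosen, the reticulation's label is tied to that parent's and every
    other constraint is a strict inequality, so feasibility reduces to
    acyclicity of the contracted strict-constraint digraph.  All
    ``∏ d⁻(r)`` donor choices are tried; choices in which some vertex
    would donate along all of its outgoing arcs (leaving the donating
    lineage without a tree continuation) are skipped.
    """
    _check_network(network)
    rets = sorted(network.reticulations())
    rset = set(rets)
    donor_choices = [sorted(network.parents(r) - rset) for r in rets]
    if any(not c for c in donor_choices):
        return None
    leaves = network.leaves()
    verts = sorted(network.vertices)
    for combo in itertools.product(*donor_choices):
        donated = {}
        for r, donor in zip(rets, combo):
            donated.setdefault(donor, set()).add(r)
        if any(
            v not in leaves and network.children(v)
            and network.children(v) <= donated.get(v, set())
            for v in verts
        ):
            continue
        # union-find over equal-label ties
        parent = {v: v for v in verts}

        def find(v):
            while parent[v] != v:
                parent[v] = parent[parent[v]]
                v = parent[v]
            return v

        for r, donor in zip(rets, combo):
            ru, du = find(r), find(donor)
            if ru != du:
                parent[ru] = du
        strict = nx.DiGraph()
        strict.add_nodes_from(find(v) for v in verts)
        ok = True
        for (u, v) in network.arcs:
            if v in rets and combo[rets.index(v)] == u:
                continue  # the tied (equal-label) arc
            cu, cv = find(u), find(v)
            if cu == cv:
                ok = False
                break
            strict.add_edge(cu, cv)
        if not ok or not nx.is_directed_acyclic_graph(strict):
            continue
        level = {}
        for c in nx.topological_sort(strict):
            level[c] = max((level[p] + 1 for p in strict.predecessors(c)), default=0)
        labelling = {v: level[find(v)] for v in verts}
        if verify_hgt_labelling(network, labelling):
            return labelling
    return None
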