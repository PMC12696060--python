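"""Mixed-graph data model for (multi-)semi-directed phylogenetic networks.

A mixed graph ``G = (V, E, A)`` has a vertex set ``V``, a set ``E`` of
undirected edges and a set ``A`` of directed arcs.  Self-loops, parallel
edge/arc pairs and antiparallel arc pairs are forbidden.  Phylogenetic
semantics enter through the optional taxon set ``X``: a semi-directed
network on ``X`` is a mixed graph obtained from a rooted, fully directed
network by forgetting the orientation of every non-reticulation arc and
suppressing the degree-2 vertices this creates.  This module provides the
graph container together with the purely structural primitives that the
recognition and classification layers are built from: degree profiles,
vertex roles, undirected components, cycle machinery, subdivision and
suppression, and the semi-deorientation map itself.

Vertex labels are opaque strings.  All operations preserve labels of
surviving vertices, so round trips (orient, then deorient) can be checked
by strict equality rather than isomorphism.  Fresh vertices created by
subdivision are labelled ``⊥0``, ``⊥1``, ... and never collide with user
labels containing no ``⊥``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "MixedGraph",
    "DegreeProfile",
    "GraphError",
    "build_graph",
    "degree_profile",
    "vertex_roles",
    "undirected_components",
    "source_components",
    "sink_components",
    "is_pendant_subtree",
    "find_semi_directed_cycle",
    "enumerate_cycles",
    "cycle_sinks",
    "is_semi_directed_cycle",
    "edge_path_between",
    "wedge_path_exists",
    "subdivide",
    "suppress",
    "semi_deorient",
    "fresh_labels",
]


class GraphError(ValueError):
    """Raised for structurally invalid mixed graphs or invalid operations."""


@dataclass(frozen=True)
class DegreeProfile:
    """Degree counts of a vertex: ``total = indeg + outdeg + edgedeg``."""

    total: int
    indeg: int
    outdeg: int
    edgedeg: int

    def __post_init__(self) -> None:
        if self.total != self.indeg + self.outdeg + self.edgedeg:
            raise GraphError("inconsistent degree profile")


def _norm_edge(u: str, v: str) -> frozenset:
    return frozenset((u, v))


@dataclass(frozen=True)
class MixedGraph:
    """An immutable mixed graph with an optional taxon set.

    Construct through :func:`build_graph`, which validates the structural
    invariants.  ``taxa`` defaults to the structural leaf set at
    construction time; it is carried along explicitly because reductions
    (e.g. cherry picking) can turn taxa into roots or isolated vertices
    while they remain taxa.
    """

    vertices: frozenset
    edges: frozenset  # of frozenset pairs
    arcs: frozenset  # of (tail, head) tuples
    taxa: frozenset

    # -- adjacency helpers -------------------------------------------------

    def edge_neighbors(self, v: str) -> set:
        return {next(iter(e - {v})) for e in self.edges if v in e}

    def parents(self, v: str) -> set:
        return {u for (u, w) in self.arcs if w == v}

    def children(self, v: str) -> set:
        return {w for (u, w) in self.arcs if u == v}

    def neighbors(self, v: str) -> set:
        return self.edge_neighbors(v) | self.parents(v) | self.children(v)

    def has_edge(self, u: str, v: str) -> bool:
        return _norm_edge(u, v) in self.edges

    def has_arc(self, u: str, v: str) -> bool:
        return (u, v) in self.arcs

    def adjacent(self, u: str, v: str) -> bool:
        return self.has_edge(u, v) or self.has_arc(u, v) or self.has_arc(v, u)

    def degree(self, v: str) -> DegreeProfile:
        return degree_profile(self, v)

    def leaves(self) -> set:
        """Structural leaf set: ``d = dᵉ = 1`` or ``d = d⁻ = 1``."""
        out = set()
        for v in self.vertices:
            d = degree_profile(self, v)
            if d.total == 1 and (d.edgedeg == 1 or d.indeg == 1):
                out.add(v)
        return out

    def reticulations(self) -> set:
        return {v for v in self.vertices if degree_profile(self, v).indeg > 1}

    def roots(self) -> set:
        """Vertices with ``d⁺ = d`` (isolated vertices included)."""
        out = set()
        for v in self.vertices:
            d = degree_profile(self, v)
            if d.outdeg == d.total:
                out.add(v)
        return out

    def replace(self, **kw) -> "MixedGraph":
        data = {
            "vertices": self.vertices,
            "edges": self.edges,
            "arcs": self.arcs,
            "taxa": self.taxa,
        }
        data.update(kw)
        return MixedGraph(**data)

    def __repr__(self) -> str:  # compact, deterministic
        return (
            f"MixedGraph(|V|={len(self.vertices)}, |E|={len(self.edges)}, "
            f"|A|={len(self.arcs)}, X={sorted(self.taxa)})"
        )


def fresh_labels(graph: MixedGraph, count: int = 1) -> list:
    """Labels ``⊥0``, ``⊥1``, ... not already used in *graph*."""
    used = graph.vertices
    out, i = [], 0
    while len(out) < count:
        lab = f"⊥{i}"
        if lab not in used:
            out.append(lab)
        i += 1
    return out


def build_graph(
    vertices: Iterable[str],
    edges: Iterable[Sequence[str]] = (),
    arcs: Iterable[Sequence[str]] = (),
    taxa: Optional[Iterable[str]] = None,
) -> MixedGraph:
    """Validate and build a :class:`MixedGraph`.

    Endpoints of edges and arcs are implicitly added to the vertex set
    only if they are listed in *vertices*; otherwise a dangling-endpoint
    error is raised.  ``taxa`` defaults to the structural leaf set.
    """
    vset = frozenset(str(v) for v in vertices)
    eset = set()
    aset = set()
    for e in edges:
        u, v = (str(x) for x in e)
        if u == v:
            raise GraphError(f"self-loop at {u!r}")
        if u not in vset or v not in vset:
            raise GraphError(f"dangling endpoint in edge {{{u}, {v}}}")
        key = _norm_edge(u, v)
        if key in eset:
            raise GraphError(f"duplicate edge {{{u}, {v}}}")
        eset.add(key)
    for a in arcs:
        u, v = (str(x) for x in a)
        if u == v:
            raise GraphError(f"self-loop at {u!r}")
        if u not in vset or v not in vset:
            raise GraphError(f"dangling endpoint in arc ({u}, {v})")
        if (u, v) in aset:
            raise GraphError(f"duplicate arc ({u}, {v})")
        if (v, u) in aset:
            raise GraphError(f"antiparallel arcs between {u!r} and {v!r}")
        if _norm_edge(u, v) in eset:
            raise GraphError(f"parallel edge/arc pair between {u!r} and {v!r}")
        aset.add((u, v))
    g = MixedGraph(vset, frozenset(eset), frozenset(aset), frozenset())
    if taxa is None:
        tset = frozenset(g.leaves())
    else:
        tset = frozenset(str(t) for t in taxa)
        if not tset <= vset:
            raise GraphError("taxa must be a subset of the vertex set")
    return g.replace(taxa=tset)


def degree_profile(graph: MixedGraph, v: str) -> DegreeProfile:
    if v not in graph.vertices:
        raise GraphError(f"unknown vertex {v!r}")
    indeg = sum(1 for a in graph.arcs if a[1] == v)
    outdeg = sum(1 for a in graph.arcs if a[0] == v)
    edgedeg = sum(1 for e in graph.edges if v in e)
    return DegreeProfile(indeg + outdeg + edgedeg, indeg, outdeg, edgedeg)


def vertex_roles(graph: MixedGraph, v: str) -> set:
    """Role set of *v*: subset of {leaf, root, reticulation, omnian}.

    A reticulation has indegree > 1; a leaf has ``d = dᵉ = 1`` or
    ``d = d⁻ = 1``; a root has ``d⁺ = d`` (an isolated vertex counts as a
    root); an omnian has at least one outgoing arc and at most one
    incident edge.
    """
    d = degree_profile(graph, v)
    roles = set()
    if d.indeg > 1:
        roles.add("reticulation")
    if d.total == 1 and (d.edgedeg == 1 or d.indeg == 1):
        roles.add("leaf")
    if d.outdeg == d.total:
        roles.add("root")
    if d.outdeg >= 1 and d.edgedeg <= 1:
        roles.add("omnian")
    return roles


# -- components ------------------------------------------------------------


def undirected_components(graph: MixedGraph) -> list:
    """Connected components of ``(V, E)``, ignoring all arcs.

    Returned as a list of frozensets, sorted by minimum label for
    determinism.
    """
    seen = set()
    comps = []
    adj = {v: set() for v in graph.vertices}
    for e in graph.edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    for start in sorted(graph.vertices):
        if start in seen:
            continue
        comp = {start}
        queue = deque([start])
        while queue:
            x = queue.popleft()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    queue.append(y)
        seen |= comp
        comps.append(frozenset(comp))
    return comps


def source_components(graph: MixedGraph) -> list:
    """Undirected components with no incoming arcs from outside."""
    out = []
    for comp in undirected_components(graph):
        if not any(head in comp and tail not in comp for (tail, head) in graph.arcs):
            out.append(comp)
    return out


def sink_components(graph: MixedGraph) -> list:
    """Undirected components with no outgoing arcs to outside."""
    out = []
    for comp in undirected_components(graph):
        if not any(tail in comp and head not in comp for (tail, head) in graph.arcs):
            out.append(comp)
    return out


def is_pendant_subtree(graph: MixedGraph, comp: Iterable[str]) -> bool:
    """True iff the edge-subgraph induced by *comp* is a tree with at most
    one vertex having a neighbour (via edge or arc) outside *comp*."""
    cset = frozenset(comp)
    inner_edges = [e for e in graph.edges if e <= cset]
    # connectivity of the induced edge-subgraph
    if cset:
        adj = {v: set() for v in cset}
        for e in inner_edges:
            u, v = tuple(e)
            adj[u].add(v)
            adj[v].add(u)
        start = next(iter(cset))
        seen = {start}
        queue = deque([start])
        while queue:
            x = queue.popleft()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        if seen != cset:
            raise GraphError("vertex set is not connected in (V, E)")
    if len(inner_edges) != len(cset) - 1:
        return False  # connected with a surplus edge: contains a cycle
    boundary = {v for v in cset if graph.neighbors(v) - cset}
    return len(boundary) <= 1


# -- cycles ----------------------------------------------------------------


def _canonical_cycle(seq: Sequence[str]) -> tuple:
    """Canonical form of a cycle ``(v1..vp=v1)``: rotate interior to the
    minimal label, pick the lexicographically smaller direction."""
    interior = list(seq[:-1])
    best = None
    n = len(interior)
    for rot in range(n):
        for order in (interior[rot:] + interior[:rot],
                      [interior[rot]] + list(reversed(interior[rot + 1:] + interior[:rot]))):
            cand = tuple(order)
            if best is None or cand < best:
                best = cand
    return best


def _cycle_valid(graph: MixedGraph, seq: Sequence[str]) -> bool:
    if len(seq) < 4 or seq[0] != seq[-1]:
        return False
    interior = seq[:-1]
    if len(set(interior)) != len(interior):
        return False
    return all(graph.adjacent(seq[i], seq[i + 1]) for i in range(len(seq) - 1))


def is_semi_directed_cycle(graph: MixedGraph, seq: Sequence[str]) -> bool:
    """A cycle is semi-directed if, in one traversal direction, every step
    is a forward arc or an edge (both directions are tried)."""
    if not _cycle_valid(graph, seq):
        raise GraphError("not a valid cycle")
    for s in (list(seq), list(reversed(seq))):
        if all(
            graph.has_arc(s[i], s[i + 1]) or graph.has_edge(s[i], s[i + 1])
            for i in range(len(s) - 1)
        ):
            return True
    return False


def cycle_sinks(graph: MixedGraph, seq: Sequence[str]) -> set:
    """Cycle vertices whose two cycle-incident connections are both arcs
    pointing into the vertex."""
    if not _cycle_valid(graph, seq):
        raise GraphError("not a valid cycle")
    interior = list(seq[:-1])
    n = len(interior)
    sinks = set()
    for i, v in enumerate(interior):
        prev = interior[(i - 1) % n]
        nxt = interior[(i + 1) % n]
        if graph.has_arc(prev, v) and graph.has_arc(nxt, v):
            sinks.add(v)
    return sinks


def enumerate_cycles(graph: MixedGraph, max_vertices: int = 18) -> list:
    """All simple cycles (any mix of edge/arc steps, either direction),
    up to rotation and reflection.  Exponential; guarded by size.

    Returns canonical interior tuples; use ``tuple + (tuple[0],)`` to get
    a sequence acceptable to :func:`cycle_sinks`.
    """
    if len(graph.vertices) > max_vertices:
        raise GraphError(f"graph too large for cycle enumeration (> {max_vertices})")
    found = set()
    adj = {v: sorted(graph.neighbors(v)) for v in graph.vertices}

    def extend(path: list, start: str) -> None:
        tail = path[-1]
        for nxt in adj[tail]:
            if nxt == start and len(path) >= 3:
                found.add(_canonical_cycle(path + [start]))
            elif nxt > start and nxt not in path:
                extend(path + [nxt], start)

    for start in sorted(graph.vertices):
        extend([start], start)
    return sorted(found)


def find_semi_directed_cycle(graph: MixedGraph) -> Optional[tuple]:
    """Return a witness semi-directed cycle ``(v1,..,vp=v1)`` or None.

    Near-linear strategy: a pure-edge cycle of ``(V, E)`` is itself
    semi-directed; otherwise contract each undirected component to a
    single node, keep arcs between components (arcs inside a component
    become self-loops), and lift any directed cycle of the contraction
    back to a simple semi-directed cycle by stitching edge-paths inside
    the components.
    """
    comps = undirected_components(graph)
    comp_of = {}
    for i, comp in enumerate(comps):
        for v in comp:
            comp_of[v] = i

    # 1. pure-edge cycle?
    cyc = _edge_cycle(graph)
    if cyc is not None:
        return cyc

    # 2. contracted digraph
    darcs = {}
    self_loops = []
    for (u, v) in sorted(graph.arcs):
        cu, cv = comp_of[u], comp_of[v]
        if cu == cv:
            self_loops.append((u, v))
        else:
            darcs.setdefault((cu, cv), (u, v))
    if self_loops:
        u, v = self_loops[0]
        # arc u->v plus edge-path v..u inside the component
        path = edge_path_between(graph, v, u)
        return tuple([u] + list(path))
    # directed cycle among components (iterative DFS, three colors)
    succ = {}
    for (cu, cv) in darcs:
        succ.setdefault(cu, []).append(cv)
    state = {}
    stack_path: list = []

    def dfs(c: int) -> Optional[list]:
        state[c] = 1
        stack_path.append(c)
        for d in sorted(succ.get(c, ())):
            if state.get(d, 0) == 1:
                i = stack_path.index(d)
                return stack_path[i:]
            if state.get(d, 0) == 0:
                res = dfs(d)
                if res is not None:
                    return res
        stack_path.pop()
        state[c] = 2
        return None

    comp_cycle = None
    for c in range(len(comps)):
        if state.get(c, 0) == 0:
            comp_cycle = dfs(c)
            if comp_cycle is not None:
                break
    if comp_cycle is None:
        return None
    # lift: stitch arcs between consecutive components with edge-paths
    k = len(comp_cycle)
    arcs_used = [darcs[(comp_cycle[i], comp_cycle[(i + 1) % k])] for i in range(k)]
    seq: list = []
    for i in range(k):
        tail, head = arcs_used[i]
        # edge-path from the head of the previous arc to this arc's tail
        prev_head = arcs_used[i - 1][1]
        path = edge_path_between(graph, prev_head, tail)
        seq.extend(path[:-1])
        seq.append(tail)
    seq.append(seq[0])
    # seq alternates tails/heads correctly; each step is an edge or the arc
    return tuple(seq)


def _edge_cycle(graph: MixedGraph) -> Optional[tuple]:
    """A simple cycle using only edges, or None."""
    adj = {v: set() for v in graph.vertices}
    for e in graph.edges:
        u, v = tuple(e)
        adj[u].add(v)
        adj[v].add(u)
    visited = set()
    for start in sorted(graph.vertices):
        if start in visited:
            continue
        parent = {start: None}
        order = [start]
        queue = deque([start])
        while queue:
            x = queue.popleft()
            visited.add(x)
            for y in sorted(adj[x]):
                if y not in parent:
                    parent[y] = x
                    order.append(y)
                    queue.append(y)
                elif parent[x] != y and parent.get(y) != x:
                    # found a cycle through x and y: join their tree paths
                    def up(z):
                        path = [z]
                        while parent[path[-1]] is not None:
                            path.append(parent[path[-1]])
                        return path

                    px, py = up(x), up(y)
                    common = None
                    sx, sy = set(px), set(py)
                    for z in px:
                        if z in sy:
                            common = z
                            break
                    ix, iy = px.index(common), py.index(common)
                    cyc = px[: ix + 1] + list(reversed(py[:iy]))
                    return tuple(cyc + [cyc[0]])
    return None


def edge_path_between(graph: MixedGraph, u: str, v: str) -> Optional[tuple]:
    """Shortest path from *u* to *v* using only edges, or None.

    The trivial path ``(u,)`` is returned when ``u == v``.
    """
    if u not in graph.vertices or v not in graph.vertices:
        raise GraphError("unknown vertex")
    if u == v:
        return (u,)
    adj = {w: set() for w in graph.vertices}
    for e in graph.edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    parent = {u: None}
    queue = deque([u])
    while queue:
        x = queue.popleft()
        for y in sorted(adj[x]):
            if y not in parent:
                parent[y] = x
                if y == v:
                    path = [v]
                    while parent[path[-1]] is not None:
                        path.append(parent[path[-1]])
                    return tuple(reversed(path))
                queue.append(y)
    return None


def wedge_path_exists(graph: MixedGraph, u: str, v: str, max_vertices: int = 18) -> bool:
    """Oracle: does a ∧-path between *u* and *v* exist?

    A ∧-path has an apex from which semi-directed paths run outward to
    both endpoints.  This checks, for every candidate apex ``w``, whether
    two vertex-disjoint (except at ``w``) semi-directed paths run from
    ``w`` to ``u`` and to ``v``, by backtracking.  Trivial paths are
    allowed (``w`` may equal ``u`` or ``v``).
    """
    if len(graph.vertices) > max_vertices:
        raise GraphError(f"graph too large for ∧-path oracle (> {max_vertices})")
    if u not in graph.vertices or v not in graph.vertices:
        raise GraphError("unknown vertex")
    if u == v:
        return True

    def paths_from(w: str, target: str, banned: frozenset) -> Iterator[frozenset]:
        """Yield vertex sets of semi-directed paths w..target avoiding banned."""
        def rec(x: str, used: set) -> Iterator[frozenset]:
            if x == target:
                yield frozenset(used)
                return
            for y in sorted(graph.edge_neighbors(x) | graph.children(x)):
                if y in used or y in banned:
                    continue
                used.add(y)
                yield from rec(y, used)
                used.remove(y)

        yield from rec(w, {w})

    for w in sorted(graph.vertices):
        for p1 in paths_from(w, u, frozenset({v})):
            banned = p1 - {w}
            for _ in paths_from(w, v, banned):
                return True
    return False


# -- subdivision / suppression / semi-deorientation ------------------------


def subdivide(graph: MixedGraph, element, label: Optional[str] = None):
    """Subdivide an edge or arc; returns ``(new_graph, new_vertex)``.

    An edge ``{u,v}`` becomes edges ``{u,w}, {w,v}``; an arc ``(u,v)``
    becomes an edge ``{u,w}`` plus an arc ``(w,v)``.
    """
    w = label if label is not None else fresh_labels(graph)[0]
    if w in graph.vertices:
        raise GraphError(f"label {w!r} already in use")
    if isinstance(element, (frozenset, set)):
        key = frozenset(element)
        if key not in graph.edges:
            raise GraphError(f"edge {sorted(element)} not in graph")
        u, v = sorted(key)
        return (
            graph.replace(
                vertices=graph.vertices | {w},
                edges=(graph.edges - {key}) | {_norm_edge(u, w), _norm_edge(w, v)},
            ),
            w,
        )
    u, v = element
    if (u, v) not in graph.arcs:
        raise GraphError(f"arc ({u}, {v}) not in graph")
    return (
        graph.replace(
            vertices=graph.vertices | {w},
            edges=graph.edges | {_norm_edge(u, w)},
            arcs=(graph.arcs - {(u, v)}) | {(w, v)},
        ),
        w,
    )


def suppress(graph: MixedGraph, v: str) -> MixedGraph:
    """Suppress a degree-2 vertex, joining its two incident elements.

    The four cases: edge+edge -> edge; arc-in+arc-out -> arc;
    edge+arc-out -> arc; arc-in+edge -> edge.  A vertex with two incoming
    or two outgoing arcs is not suppressible.  Raises if the replacement
    would create a parallel or antiparallel pair.
    """
    d = degree_profile(graph, v)
    if d.total != 2:
        raise GraphError(f"{v!r} is not a degree-2 vertex")
    if d.indeg == 2 or d.outdeg == 2:
        raise GraphError(f"{v!r} is unsuppressible (two incoming or two outgoing arcs)")
    in_arcs = sorted(a for a in graph.arcs if a[1] == v)
    out_arcs = sorted(a for a in graph.arcs if a[0] == v)
    inc_edges = sorted((sorted(e) for e in graph.edges if v in e))
    new_edges = set(graph.edges) - {frozenset(e) for e in inc_edges}
    new_arcs = set(graph.arcs) - set(in_arcs) - set(out_arcs)

    def other(edge_pair):
        a, b = edge_pair
        return b if a == v else a

    if len(inc_edges) == 2:
        u, w = other(inc_edges[0]), other(inc_edges[1])
        repl = ("edge", u, w)
    elif in_arcs and out_arcs:
        repl = ("arc", in_arcs[0][0], out_arcs[0][1])
    elif out_arcs:  # edge {u,v} + arc (v,w) -> arc (u,w)
        repl = ("arc", other(inc_edges[0]), out_arcs[0][1])
    else:  # arc (u,v) + edge {v,w} -> edge {u,w}
        repl = ("edge", in_arcs[0][0], other(inc_edges[0]))

    kind, a, b = repl
    if a == b:
        raise GraphError("suppression would create a self-loop")
    if _norm_edge(a, b) in new_edges or (a, b) in new_arcs or (b, a) in new_arcs:
        raise GraphError("parallel forbidden: suppression would create a parallel pair")
    if kind == "edge":
        new_edges.add(_norm_edge(a, b))
    else:
        new_arcs.add((a, b))
    return graph.replace(
        vertices=graph.vertices - {v},
        edges=frozenset(new_edges),
        arcs=frozenset(new_arcs),
        taxa=graph.taxa - {v},
    )


def semi_deorient(network: MixedGraph) -> MixedGraph:
    """Semi-deorientation of a fully directed (multi-rooted) network.

    Every arc whose head has indegree 1 becomes an edge; afterwards every
    degree-2 vertex that is suppressible is suppressed.  (A degree-2 root
    whose two arcs both point at reticulations keeps them as arcs and is
    therefore not suppressible; it survives.)  Labels of surviving
    vertices are preserved.  Raises on suppressions that would create
    parallel pairs.
    """
    indeg = {v: 0 for v in network.vertices}
    for (_, h) in network.arcs:
        indeg[h] += 1
    new_edges = set(network.edges)
    new_arcs = set()
    for (t, h) in network.arcs:
        if indeg[h] == 1:
            new_edges.add(_norm_edge(t, h))
        else:
            new_arcs.add((t, h))
    g = network.replace(edges=frozenset(new_edges), arcs=frozenset(new_arcs))
    # suppress degree-2 vertices (only former roots qualify in valid input)
    changed = True
    while changed:
        changed = False
        for v in sorted(g.vertices):
            d = degree_profile(g, v)
            if d.total == 2 and d.indeg != 2 and d.outdeg != 2:
                g = suppress(g, v)
                changed = True
                break
    return g
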