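"""Recognition of (multi-)semi-directed networks.

A mixed graph is *multi-semi-directed* when it can be obtained from a
multi-rooted, fully directed network by semi-deorientation.  Three
equivalent decision routes are provided:

* a degree/cycle/edge-path characterization (``check_recognition_conditions``):
  no degree-2 vertices and ``d⁻ ∈ {0, d−1}`` everywhere, no semi-directed
  cycle, and no non-trivial edge-path between two reticulations;
* a sink-based characterization (``check_sink_conditions``, an exponential
  oracle): every cycle has a sink and every sink component is a pendant
  subtree;
* a constructive route (``is_multi_semi_directed``): root one vertex per
  source component, orient all edges away from the roots, and verify that
  the result is a multi-rooted network whose semi-deorientation equals
  the input.

The constructive route is the production recognizer (near-linear); the
other two serve as cross-checks.  ``is_semi_directed`` additionally
demands a single source component, equivalently a ∧-path between every
vertex pair.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

from .core import (
    GraphError,
    MixedGraph,
    cycle_sinks,
    degree_profile,
    enumerate_cycles,
    find_semi_directed_cycle,
    is_pendant_subtree,
    semi_deorient,
    sink_components,
    source_components,
    undirected_components,
    wedge_path_exists,
    edge_path_between,
)

__all__ = [
    "ConditionReport",
    "check_recognition_conditions",
    "check_sink_conditions",
    "orient_from_roots",
    "is_multi_semi_directed",
    "is_semi_directed",
    "reticulation_number",
    "root_count",
]


@dataclass(frozen=True)
class ConditionReport:
    """Outcome of one condition: holds/fails plus a witness for failures."""

    holds: bool
    witness: object = None

    def __bool__(self) -> bool:
        return self.holds


def _degree_condition(graph: MixedGraph) -> ConditionReport:
    """d(v) != 2 and d⁻(v) in {0, d(v)-1} for all v."""
    for v in sorted(graph.vertices):
        d = degree_profile(graph, v)
        if d.total == 2 or d.indeg not in (0, d.total - 1):
            return ConditionReport(False, v)
    return ConditionReport(True)


def check_recognition_conditions(graph: MixedGraph) -> dict:
    """The degree / semi-directed-cycle / reticulation-edge-path test.

    Returns ``{"I": .., "II": .., "III": ..}`` of :class:`ConditionReport`;
    the graph is multi-semi-directed iff all three hold.  Witnesses: the
    offending vertex (I), a semi-directed cycle (II), or an edge-path
    joining two reticulations (III).
    """
    rep = {"I": _degree_condition(graph)}
    cyc = find_semi_directed_cycle(graph)
    rep["II"] = ConditionReport(cyc is None, cyc)
    rep["III"] = ConditionReport(True)
    rets = graph.reticulations()
    for comp in undirected_components(graph):
        inside = sorted(rets & comp)
        if len(inside) >= 2:
            path = edge_path_between(graph, inside[0], inside[1])
            rep["III"] = ConditionReport(False, path)
            break
    return rep


def check_sink_conditions(graph: MixedGraph, max_vertices: int = 18) -> dict:
    """Oracle test via cycle sinks and pendant sink components.

    ``Ci`` equals condition I above; ``Cii`` demands a sink on every
    cycle (all cycles enumerated, exponential); ``Ciii`` demands that
    every sink component is a pendant subtree.
    """
    rep = {"Ci": _degree_condition(graph)}
    rep["Cii"] = ConditionReport(True)
    for interior in enumerate_cycles(graph, max_vertices=max_vertices):
        seq = interior + (interior[0],)
        if not cycle_sinks(graph, seq):
            rep["Cii"] = ConditionReport(False, seq)
            break
    rep["Ciii"] = ConditionReport(True)
    for comp in sink_components(graph):
        if not is_pendant_subtree(graph, comp):
            rep["Ciii"] = ConditionReport(False, frozenset(comp))
            break
    return rep


def orient_from_roots(graph: MixedGraph, roots) -> Optional[MixedGraph]:
    """Orient every edge of *graph* away from *roots* by breadth-first
    traversal (following edges in either direction once oriented, and
    arcs forward).  Returns the oriented graph, or None if some edge
    cannot be reached and oriented.
    """
    orientation = {}  # frozenset edge -> (tail, head)
    seen = set()
    queue = deque(sorted(roots))
    seen.update(queue)
    while queue:
        x = queue.popleft()
        for y in sorted(graph.edge_neighbors(x)):
            e = frozenset((x, y))
            if e not in orientation:
                orientation[e] = (x, y)
                if y not in seen:
                    seen.add(y)
                    queue.append(y)
        for y in sorted(graph.children(x)):
            if y not in seen:
                seen.add(y)
                queue.append(y)
    if len(orientation) != len(graph.edges):
        return None
    return graph.replace(
        edges=frozenset(),
        arcs=graph.arcs | frozenset(orientation.values()),
    )


def is_multi_semi_directed(graph: MixedGraph, return_rooting: bool = False):
    """Constructive recognizer: root the minimum-label vertex of every
    source component, orient, and verify the round trip.

    With ``return_rooting=True`` returns ``(verdict, oriented_or_None)``.
    """
    from .rooted import is_multi_rooted_network  # local: avoid cycle

    roots = [min(comp) for comp in source_components(graph)]
    oriented = orient_from_roots(graph, roots)
    verdict = False
    if oriented is not None and is_multi_rooted_network(oriented):
        try:
            verdict = semi_deorient(oriented) == graph
        except GraphError:
            verdict = False
    if return_rooting:
        return verdict, (oriented if verdict else None)
    return verdict


def is_semi_directed(graph: MixedGraph) -> bool:
    """True iff *graph* is the semi-deorientation of a 1-rooted network:
    multi-semi-directed with a single source component."""
    return is_multi_semi_directed(graph) and len(source_components(graph)) == 1


def is_semi_directed_oracle(graph: MixedGraph, max_vertices: int = 14) -> bool:
    """Small-graph oracle: degree condition, a sink on every cycle, and a
    ∧-path between every pair of vertices."""
    if not _degree_condition(graph):
        return False
    for interior in enumerate_cycles(graph, max_vertices=max_vertices):
        if not cycle_sinks(graph, interior + (interior[0],)):
            return False
    verts = sorted(graph.vertices)
    for i, u in enumerate(verts):
        for v in verts[i + 1:]:
            if not wedge_path_exists(graph, u, v, max_vertices=max_vertices):
                return False
    return True


def _require_msd(network: MixedGraph) -> None:
    if not is_multi_semi_directed(network):
        raise GraphError("not a multi-semi-directed network")


def reticulation_number(network: MixedGraph) -> int:
    """|A| − |R|: arcs in excess of one per reticulation."""
    _require_msd(network)
    return len(network.arcs) - len(network.reticulations())


def root_count(network: MixedGraph) -> int:
    """Number of roots of every rooting: ``|V| − |R| − |E|``."""
    _require_msd(network)
    return len(network.vertices) - len(network.reticulations()) - len(network.edges)
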