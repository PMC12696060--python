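"""Rootings of multi-semi-directed networks.

A *rooting* of a network ``N`` is a multi-rooted network whose
semi-deorientation is ``N``.  Root locations form a *root
configuration* ``(V', E', A')``: roots may sit on vertices of ``N``, on
subdivisions of edges, or on subdivisions of arcs.  A configuration is
feasible exactly when every part lies in (or leaves) a source component
and every source component carries exactly one root choice; this yields
a finite, easily enumerable space of rootings — one per configuration,
since sliding a subdivision point along its edge only renames the
rooting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .core import (
    GraphError,
    MixedGraph,
    semi_deorient,
    source_components,
    subdivide,
)
from .recognition import is_multi_semi_directed, orient_from_roots
from .rooted import is_multi_rooted_network

__all__ = [
    "RootConfiguration",
    "Rooting",
    "is_valid_root_configuration",
    "apply_root_configuration",
    "enumerate_root_configurations",
    "enumerate_rootings",
    "nice_rooting",
    "is_nice_rooting",
    "enumerate_nice_rootings",
    "is_rooting_of",
]


@dataclass(frozen=True)
class RootConfiguration:
    """Chosen root locations: vertices V', edges E', arcs A' of N."""

    root_vertices: frozenset = frozenset()
    root_edges: frozenset = frozenset()  # of frozenset pairs
    root_arcs: frozenset = frozenset()  # of (tail, head) tuples

    @classmethod
    def of(cls, vertices=(), edges=(), arcs=()) -> "RootConfiguration":
        return cls(
            frozenset(vertices),
            frozenset(frozenset(e) for e in edges),
            frozenset(tuple(a) for a in arcs),
        )

    def size(self) -> int:
        return len(self.root_vertices) + len(self.root_edges) + len(self.root_arcs)


@dataclass(frozen=True)
class Rooting:
    """A rooting of ``origin``: a fully directed multi-rooted network
    whose semi-deorientation is ``origin`` (by label equality), together
    with the provenance of fresh subdivision roots."""

    network: MixedGraph
    origin: MixedGraph
    configuration: RootConfiguration
    subdivision_map: dict = field(default_factory=dict, compare=False)

    def roots(self) -> set:
        return self.network.roots()


def is_rooting_of(directed: MixedGraph, origin: MixedGraph) -> bool:
    """Is *directed* a multi-rooted network whose semi-deorientation is
    *origin* (strict label equality)?"""
    if not is_multi_rooted_network(directed):
        return False
    try:
        return semi_deorient(directed) == origin
    except GraphError:
        return False


def _component_of(comps, item) -> Optional[frozenset]:
    for c in comps:
        if item in c:
            return c
    return None


def is_valid_root_configuration(network: MixedGraph, cfg: RootConfiguration) -> bool:
    """Feasibility test: (1) every chosen vertex/edge lies in a source
    component and every chosen arc leaves one; (2) each source component
    carries exactly one choice."""
    if not cfg.root_vertices <= network.vertices:
        raise GraphError("configuration names unknown vertices")
    if not cfg.root_edges <= network.edges:
        raise GraphError("configuration names unknown edges")
    if not cfg.root_arcs <= network.arcs:
        raise GraphError("configuration names unknown arcs")
    comps = source_components(network)
    counts = {c: 0 for c in comps}
    for v in cfg.root_vertices:
        c = _component_of(comps, v)
        if c is None:
            return False
        counts[c] += 1
    for e in cfg.root_edges:
        u, _ = tuple(e)
        c = _component_of(comps, u)
        if c is None or not e <= c:
            return False
        counts[c] += 1
    for (t, h) in cfg.root_arcs:
        c = _component_of(comps, t)
        if c is None:
            return False
        counts[c] += 1
    return all(n == 1 for n in counts.values())


def apply_root_configuration(network: MixedGraph, cfg: RootConfiguration) -> Rooting:
    """Construct the rooting with configuration *cfg*: subdivide every
    chosen edge/arc (the fresh vertex becomes a root), orient all edges
    away from the roots, and verify the round trip."""
    if not is_valid_root_configuration(network, cfg):
        raise GraphError("invalid root configuration")
    g = network
    submap = {}
    for e in sorted(cfg.root_edges, key=sorted):
        g, w = subdivide(g, e)
        submap[w] = frozenset(e)
    for a in sorted(cfg.root_arcs):
        g, w = subdivide(g, a)
        submap[w] = tuple(a)
    roots = sorted(cfg.root_vertices) + sorted(submap)
    oriented = orient_from_roots(g, roots)
    if oriented is None or not is_rooting_of(oriented, network):
        raise GraphError("configuration does not yield a rooting")
    return Rooting(oriented, network, cfg, submap)


def enumerate_root_configurations(
    network: MixedGraph, leaf_preserving: bool = False
) -> Iterator[RootConfiguration]:
    """All feasible root configurations: the cross-product, over source
    components, of (vertices of C) ∪ (edges inside C) ∪ (outgoing arcs
    of C).

    With ``leaf_preserving`` only configurations whose rooting has leaf
    set exactly X are yielded (needed for forest-based membership, where
    no taxon may become a root).
    """
    if not is_multi_semi_directed(network):
        raise GraphError("not a multi-semi-directed network")
    comps = source_components(network)
    per_comp = []
    for c in comps:
        opts = [("v", v) for v in sorted(c)]
        opts += [("e", tuple(sorted(e))) for e in sorted(
            (e for e in network.edges if e <= c), key=sorted)]
        opts += [("a", a) for a in sorted(network.arcs) if a[0] in c]
        per_comp.append(opts)
    for combo in itertools.product(*per_comp):
        cfg = RootConfiguration.of(
            vertices=[x for k, x in combo if k == "v"],
            edges=[x for k, x in combo if k == "e"],
            arcs=[x for k, x in combo if k == "a"],
        )
        if leaf_preserving:
            rooting = apply_root_configuration(network, cfg)
            if rooting.network.leaves() != set(network.taxa):
                continue
        yield cfg


def enumerate_rootings(
    network: MixedGraph, leaf_preserving: bool = False
) -> Iterator[Rooting]:
    for cfg in enumerate_root_configurations(network, leaf_preserving):
        yield apply_root_configuration(network, cfg)


def is_nice_rooting(rooting: Rooting) -> bool:
    """Nice: every root is a non-taxon vertex of N, or subdivides an arc
    of N whose tail is a taxon."""
    n = rooting.origin
    for r in rooting.roots():
        if r in n.vertices:
            if r in n.taxa:
                return False
        else:
            elem = rooting.subdivision_map.get(r)
            if not (isinstance(elem, tuple) and elem[0] in n.taxa):
                return False
    return True


def nice_rooting(network: MixedGraph) -> Rooting:
    """A rooting whose roots avoid taxa: per source component prefer a
    non-taxon vertex, then an outgoing arc with a taxon tail.

    Every multi-semi-directed network admits one, except for the
    degenerate case of a source component consisting entirely of taxa
    with no outgoing arcs (e.g. a single edge on two taxa); there the
    minimum-label vertex is rooted instead and the result simply fails
    :func:`is_nice_rooting`.
    """
    if not is_multi_semi_directed(network):
        raise GraphError("not a multi-semi-directed network")
    vertices, arcs = [], []
    for c in source_components(network):
        non_taxa = sorted(set(c) - set(network.taxa))
        if non_taxa:
            vertices.append(non_taxa[0])
            continue
        out = sorted(a for a in network.arcs if a[0] in c)
        if out:
            arcs.append(out[0])
        else:
            vertices.append(min(c))  # degenerate all-taxon component
    cfg = RootConfiguration.of(vertices=vertices, arcs=arcs)
    return apply_root_configuration(network, cfg)


def enumerate_nice_rootings(network: MixedGraph) -> Iterator[Rooting]:
    """All rootings that are nice per source component: the root is a
    non-taxon vertex, or subdivides an outgoing arc with a taxon tail.

    A source component made entirely of taxa with no outgoing arcs
    admits no nice root; as in :func:`nice_rooting`, such components
    fall back to rooting one of their vertices, so the enumeration stays
    non-empty whenever the network has a rooting at all.
    """
    if not is_multi_semi_directed(network):
        raise GraphError("not a multi-semi-directed network")
    per_comp = []
    for c in source_components(network):
        opts = [("v", v) for v in sorted(set(c) - set(network.taxa))]
        opts += [("a", a) for a in sorted(network.arcs)
                 if a[0] in c and a[0] in network.taxa]
        if not opts:
            opts = [("v", v) for v in sorted(c)]  # degenerate fallback
        per_comp.append(opts)
    for combo in itertools.product(*per_comp):
        cfg = RootConfiguration.of(
            vertices=[x for kind, x in combo if kind == "v"],
            arcs=[x for kind, x in combo if kind == "a"],
        )
        yield apply_root_configuration(network, cfg)
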