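"""File formats, random generators and named fixtures.

The plain-text ``sdn`` format is one directive per line::

    # comment
    taxa a b c
    vertex u
    edge u v
    arc u v

``vertex`` lines are optional for vertices that appear in an edge or
arc.  Canonical output sorts directives and edge endpoints, so
``write_sdn(read_sdn(text))`` is the identity on canonical documents.

Rootings can be exchanged as extended Newick, with reticulations shared
between parents through ``#H`` tags; multi-rooted networks are written
as one eNewick line per root.

The random generator grows ``k`` rooted binary trees and adds
reticulation arcs between subdivided tree arcs, rejecting placements
that would close a directed cycle or put two reticulation children
under a degree-2 root (whose semi-deorientation would retain a
degree-2 vertex).  Its semi-deorientations are the multi-semi-directed
instances used throughout the test suite; ``perturb`` manufactures
near-miss negatives that violate one recognition condition at a time.
"""

from __future__ import annotations

import random
import re
from typing import Dict, Optional, Tuple

from .core import (
    GraphError,
    MixedGraph,
    build_graph,
    degree_profile,
    semi_deorient,
    subdivide,
)
from .fixtures import fixtures

__all__ = [
    "read_sdn",
    "write_sdn",
    "write_enewick",
    "read_enewick",
    "random_multi_rooted_network",
    "random_msd",
    "perturb",
    "fixtures",
]


# -- sdn format ------------------------------------------------------------


def read_sdn(text: str) -> MixedGraph:
    vertices, edges, arcs = set(), [], []
    taxa = None
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        kind, args = parts[0], parts[1:]
        if kind == "taxa":
            taxa = set(args) if taxa is None else (taxa | set(args))
        elif kind == "vertex":
            if len(args) != 1:
                raise GraphError(f"line {ln}: vertex takes one label")
            vertices.add(args[0])
        elif kind == "edge":
            if len(args) != 2:
                raise GraphError(f"line {ln}: edge takes two labels")
            edges.append(tuple(args))
            vertices.update(args)
        elif kind == "arc":
            if len(args) != 2:
                raise GraphError(f"line {ln}: arc takes two labels")
            arcs.append(tuple(args))
            vertices.update(args)
        else:
            raise GraphError(f"line {ln}: unknown directive {kind!r}")
    return build_graph(vertices, edges, arcs, taxa)


def write_sdn(graph: MixedGraph) -> str:
    lines = []
    # always present, so an empty taxon set is not re-inferred on read
    lines.append(("taxa " + " ".join(sorted(graph.taxa))).rstrip())
    mentioned = set()
    for e in graph.edges:
        mentioned |= set(e)
    for a in graph.arcs:
        mentioned |= set(a)
    for v in sorted(graph.vertices - mentioned):
        lines.append(f"vertex {v}")
    for e in sorted(graph.edges, key=sorted):
        u, v = sorted(e)
        lines.append(f"edge {u} {v}")
    for (u, v) in sorted(graph.arcs):
        lines.append(f"arc {u} {v}")
    return "\n".join(lines) + "\n"


# -- extended Newick -------------------------------------------------------


def write_enewick(network: MixedGraph) -> str:
    """Write a multi-rooted network (E = ∅) as extended Newick, one line
    per root, reticulations shared via ``#H`` tags."""
    if network.edges:
        raise GraphError("eNewick export requires a fully directed network")
    rets = sorted(network.reticulations())
    tag = {r: f"#H{i + 1}" for i, r in enumerate(rets)}
    expanded = set()

    def render(v: str) -> str:
        if v in tag:
            if v in expanded:
                return f"{v}{tag[v]}"
            expanded.add(v)
            kids = sorted(network.children(v))
            inner = ",".join(render(c) for c in kids)
            return (f"({inner}){v}{tag[v]}" if kids else f"{v}{tag[v]}")
        kids = sorted(network.children(v))
        if not kids:
            return v
        return "(" + ",".join(render(c) for c in kids) + ")" + v

    lines = [render(r) + ";" for r in sorted(network.roots())]
    return "\n".join(lines) + "\n"


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;]+")


def read_enewick(text: str) -> MixedGraph:
    """Parse the output of :func:`write_enewick` back into a multi-rooted
    network (labels preserved)."""
    vertices = set()
    arcs = []
    anon = [0]

    def fresh() -> str:
        anon[0] += 1
        return f"_n{anon[0]}"

    def parse_label(lab: str) -> Tuple[str, Optional[str]]:
        if "#" in lab:
            name, tag = lab.split("#", 1)
            return (name if name else f"_{tag}"), tag
        return lab, None

    for line in text.strip().split("\n"):
        line = line.strip()
        if not line:
            continue
        if not line.endswith(";"):
            raise GraphError("malformed eNewick: missing ';'")
        tokens = _TOKEN.findall(line[:-1])
        pos = [0]

        def parse_node() -> str:
            children = []
            if pos[0] < len(tokens) and tokens[pos[0]] == "(":
                pos[0] += 1
                children.append(parse_node())
                while pos[0] < len(tokens) and tokens[pos[0]] == ",":
                    pos[0] += 1
                    children.append(parse_node())
                if pos[0] >= len(tokens) or tokens[pos[0]] != ")":
                    raise GraphError("malformed eNewick: unbalanced parentheses")
                pos[0] += 1
            label = None
            if pos[0] < len(tokens) and tokens[pos[0]] not in "(),;":
                label = tokens[pos[0]]
                pos[0] += 1
            if label is None:
                name = fresh()
            else:
                name, _tag = parse_label(label)
            vertices.add(name)
            for c in children:
                arcs.append((name, c))
            return name

        parse_node()
        if pos[0] != len(tokens):
            raise GraphError("malformed eNewick: trailing tokens")
    seen = set()
    deduped = []
    for a in arcs:
        if a in seen:
            raise GraphError("malformed eNewick: repeated arc")
        seen.add(a)
        deduped.append(a)
    return build_graph(vertices, (), deduped)


# -- random generators -----------------------------------------------------


def _random_rooted_tree(rng: random.Random, leaf_names, prefix: str) -> MixedGraph:
    """A uniform-ish rooted binary tree on the given leaves (single arc
    root -> leaf when there is one leaf)."""
    leaf_names = list(leaf_names)
    counter = [0]

    def internal() -> str:
        counter[0] += 1
        return f"{prefix}i{counter[0]}"

    root = f"{prefix}root"
    vertices = set(leaf_names) | {root}
    arcs = []
    if len(leaf_names) == 1:
        arcs.append((root, leaf_names[0]))
    else:
        # grow by leaf attachment: start with a cherry, attach the rest
        sub = leaf_names[:]
        rng.shuffle(sub)
        arcs = [(root, sub[0]), (root, sub[1])]
        for leaf in sub[2:]:
            (u, v) = rng.choice(sorted(arcs))
            w = internal()
            vertices.add(w)
            arcs.remove((u, v))
            arcs += [(u, w), (w, v), (w, leaf)]
    return build_graph(vertices, (), arcs)


def _reachable(arcs, start: str) -> set:
    succ: Dict[str, list] = {}
    for (t, h) in arcs:
        succ.setdefault(t, []).append(h)
    out, stack = {start}, [start]
    while stack:
        x = stack.pop()
        for y in succ.get(x, ()):
            if y not in out:
                out.add(y)
                stack.append(y)
    return out


def random_multi_rooted_network(
    n_leaves: int,
    n_reticulations: int,
    k: int = 1,
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
    unresolve: float = 0.0,
) -> MixedGraph:
    """A random k-rooted network: k rooted binary trees on ``n_leaves``
    taxa overall, plus ``n_reticulations`` reticulation arcs added
    between subdivided tree arcs (cycle-free, and never leaving a
    degree-2 root with two reticulation children).  With ``unresolve``
    > 0, eligible internal arcs are contracted with that probability to
    produce multifurcations.
    """
    if rng is None:
        rng = random.Random(seed)
    if n_leaves < 2 or k < 1 or n_leaves < 2 * k:
        raise GraphError("need n_leaves >= 2k and k >= 1 (two leaves per root)")
    leaves = [f"x{i + 1}" for i in range(n_leaves)]
    rng.shuffle(leaves)
    sizes = [2] * k
    for _ in range(n_leaves - 2 * k):
        sizes[rng.randrange(k)] += 1
    parts, at = [], 0
    for s in sizes:
        parts.append(leaves[at: at + s])
        at += s
    vertices, arcs = set(), []
    for i, part in enumerate(parts):
        t = _random_rooted_tree(rng, part, prefix=f"T{i + 1}")
        vertices |= t.vertices
        arcs += sorted(t.arcs)
    g = build_graph(vertices, (), arcs)

    for m in range(n_reticulations):
        placed = False
        for _attempt in range(400):
            arc_list = sorted(g.arcs)
            a1 = rng.choice(arc_list)
            a2 = rng.choice(arc_list)
            if a1 == a2:
                continue
            (u1, v1), (u2, v2) = a1, a2
            # cycle: the new arc s -> t closes a loop iff u1 is below v2
            if u1 in _reachable(g.arcs, v2) or u1 == v2:
                continue
            # both chosen arcs leaving one degree-2 root: its suppression
            # in the semi-deorientation would create a parallel arc
            if u1 == u2:
                du = degree_profile(g, u1)
                if du.indeg == 0 and du.total == 2:
                    continue
            # A degree-2 root must keep at least one child that is an
            # internal non-reticulation: two reticulation children would
            # leave a degree-2 vertex in the semi-deorientation, and a
            # leaf + reticulation pair would leave a pendant degree-1
            # root-taxon with no incident edge — both outside the
            # well-behaved instance family the generator emulates.
            du2 = degree_profile(g, u2)
            if du2.indeg == 0 and du2.total == 2:
                other = g.children(u2) - {v2}
                if any(
                    degree_profile(g, c).indeg > 1 or degree_profile(g, c).total == 1
                    for c in other
                ):
                    continue
            gg, s = subdivide_arc_directed(g, a1, f"p{m + 1}")
            gg, t = subdivide_arc_directed(gg, a2, f"q{m + 1}")
            g = gg.replace(arcs=gg.arcs | {(s, t)})
            placed = True
            break
        if not placed:
            raise GraphError("could not place a reticulation (infeasible parameters)")

    if unresolve > 0:
        rets = g.reticulations()
        for (u, v) in sorted(g.arcs):
            if (
                (u, v) in g.arcs
                and v not in rets and u not in rets
                and g.children(v) and degree_profile(g, v).indeg == 1
                and rng.random() < unresolve
            ):
                moved = {(v, c) for c in g.children(v)}
                g = g.replace(
                    vertices=g.vertices - {v},
                    arcs=(g.arcs - moved - {(u, v)})
                    | {(u, c) for (_, c) in moved},
                    taxa=g.taxa - {v},
                )
    return g


def subdivide_arc_directed(g: MixedGraph, arc, label: str) -> Tuple[MixedGraph, str]:
    """Subdivide an arc of a fully directed network into two arcs
    (unlike mixed-graph subdivision, which introduces an edge)."""
    (u, v) = arc
    if (u, v) not in g.arcs:
        raise GraphError(f"arc {arc} not in graph")
    w = label
    while w in g.vertices:
        w += "'"
    return (
        g.replace(
            vertices=g.vertices | {w},
            arcs=(g.arcs - {(u, v)}) | {(u, w), (w, v)},
        ),
        w,
    )


def random_msd(
    n_leaves: int,
    n_reticulations: int,
    k: int = 1,
    seed: Optional[int] = None,
    rng: Optional[random.Random] = None,
    unresolve: float = 0.0,
) -> MixedGraph:
    """Semi-deorientation of :func:`random_multi_rooted_network`."""
    d = random_multi_rooted_network(
        n_leaves, n_reticulations, k, seed=seed, rng=rng, unresolve=unresolve
    )
    n = semi_deorient(d)
    return n.replace(taxa=d.taxa)


def perturb(graph: MixedGraph, kind: str, seed: Optional[int] = None) -> MixedGraph:
    """Damage a graph so that one recognition condition fails.

    * ``add_ret_ret_edge``: add an edge between two reticulations
      (creates a reticulation-to-reticulation edge-path);
    * ``flip_to_sd_cycle``: add an arc closing a semi-directed cycle
      between two undirected components;
    * ``make_degree2``: subdivide an edge, leaving a degree-2 vertex.
    """
    rng = random.Random(seed)
    if kind == "make_degree2":
        if not graph.edges:
            raise GraphError("perturbation inapplicable: no edges")
        e = rng.choice(sorted(graph.edges, key=sorted))
        g, _ = subdivide(graph, e)
        return g
    if kind == "add_ret_ret_edge":
        rets = sorted(graph.reticulations())
        pairs = [
            (a, b)
            for i, a in enumerate(rets)
            for b in rets[i + 1:]
            if not graph.adjacent(a, b)
        ]
        if not pairs:
            raise GraphError("perturbation inapplicable: need two non-adjacent reticulations")
        a, b = rng.choice(pairs)
        return graph.replace(edges=graph.edges | {frozenset((a, b))})
    if kind == "flip_to_sd_cycle":
        from .core import undirected_components

        comps = undirected_components(graph)
        comp_of = {v: i for i, c in enumerate(comps) for v in c}
        options = []
        for (t, h) in sorted(graph.arcs):
            for w in sorted(comps[comp_of[h]]):
                for x in sorted(comps[comp_of[t]]):
                    if w == x or graph.adjacent(w, x) or comp_of[w] == comp_of[x]:
                        continue
                    options.append((w, x))
        if not options:
            raise GraphError("perturbation inapplicable: no reverse arc available")
        w, x = rng.choice(options)
        return graph.replace(arcs=graph.arcs | {(w, x)})
    raise GraphError(f"unknown perturbation kind {kind!r}")
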