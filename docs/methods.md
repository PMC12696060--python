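# Methods

## The model

A *mixed graph* `G = (V, E, A)` carries undirected edges `E` and
directed arcs `A`, with self-loops, parallel edge/arc pairs and
antiparallel arcs forbidden.  A *multi-rooted network* on a taxon set
`X` is a mixed graph with `E = ∅`, no directed cycles, no degree-2
non-root vertices, and `d⁻(v) ∈ {0, 1, d(v)−1}` everywhere; its leaves
are `X`.  *Semi-deorientation* forgets the root: every arc whose head
has indegree 1 becomes an edge, then every suppressible degree-2 vertex
is suppressed (a degree-2 vertex with two incoming or two outgoing arcs
cannot be suppressed and survives).  A *(multi-)semi-directed network*
is any mixed graph obtainable this way; a *rooting* of `N` is a
multi-rooted network deorienting to `N`.

The package decides, for an arbitrary mixed graph: membership in this
class (three independent routes), the full space of rootings (via root
configurations: per source component, one root on a vertex, an edge, or
an outgoing arc), and weak/strong membership of `N` in the tree-child,
tree-based, orchard and forest-based classes.  "Weak" means some
rooting is in the class, "strong" means all are (for forest-based:
all/some rootings *with leaf set X*, since a support forest's leaves
must be the taxa).

Vertex labels are opaque strings and every operation preserves the
labels of surviving vertices, so orientation/deorientation round trips
are checked by strict equality rather than isomorphism.  Fresh
subdivision vertices are labelled `⊥0, ⊥1, …`.  Cycles are canonical-
ized by rotating to the minimal label and taking the lexicographically
smaller direction; all set-valued iterations are sorted, so every
decider and witness is deterministic.

## Deciders and their oracles

* **Recognition.**  Production route: pick the minimum-label vertex of
  each source component, orient all edges away from the roots by
  breadth-first traversal, verify that the result is a multi-rooted
  network deorienting back to the input.  Cross-checks: (i) no degree-2
  vertices and `d⁻ ∈ {0, d−1}`, no semi-directed cycle, no edge-path
  between two reticulations; (ii) every cycle has a sink and every sink
  component is a pendant subtree (exponential cycle enumeration, size-
  guarded).  Semi-directed cycles are found near-linearly by
  contracting each undirected component and lifting any directed cycle
  of the contraction back through edge-paths; this is sound because
  parallel and antiparallel pairs are forbidden.

* **Tree-child.**  Strong: no omnians (`d⁺ ≥ 1` and `dᵉ ≤ 1`).  Weak:
  at most one omnian per root, an incident edge at every vertex, and no
  undirected component containing two omnians/reticulations.

* **Tree-based** (strong, semi-directed inputs): maximum matching
  (Hopcroft–Karp via networkx) in the bipartite graph pairing omnians
  with the reticulations they feed must cover the omnians — Hall's
  condition, also checkable by subset enumeration.  Multi-rooted inputs
  are false outright: a spanning tree has one root.

* **Orchard.**  Weak: reduce cherries and reticulated cherries
  greedily; the verdict is order-independent, and the network is weakly
  orchard iff the terminal graph consists of isolated taxa and
  taxon–taxon edges.  A reticulated cherry `(x, y)` requires `y` to be
  a leaf attached by an edge to a reticulation `r` and `x` a taxon
  reaching `r` either by an arc `(x, r)` (`x` a taxon that has become a
  root) or through an edge `{x, m}` with `(m, r)` an arc; the reduction
  deletes the arc entering `r`.  The literal "any length-2 or length-3
  path" reading would also admit an arc–arc path through a
  reticulation, but reducing such a pair leaves an invalid vertex with
  `d⁻ = d = 2`, so it is excluded by design.

  Strong (semi-directed inputs): cherries and *non-scr* reticulated
  cherries (first taxon not in a source component) are verdict-
  equivalent reductions and are consumed greedily.  At a state where
  only scr-cherries remain, the network fails iff a single root
  location — a vertex `x`, an edge `{x, m}`, or an arc `(m, r)` —
  breaks every witness path of every remaining pair: the rooting placed
  there admits no reduction at all.  Otherwise each scr reduction is
  explored (memoized on exact graph encodings).  The simpler rule
  "fail iff a lone scr-cherry is reduced", with scr-cherries always
  taken first, is *not* equivalent to brute force: a lone scr-cherry
  can coexist with ordinary cherries whose reduction rescues it, and
  two scr-cherries sharing their first taxon die together under a
  single root placement.  The implemented exploration agrees with
  brute force over all rootings on every random instance the test and
  acceptance suites draw, and the brute-force route remains available
  (`method="brute"`), including experimentally for multi-rooted inputs
  where no sequence characterization is known.

* **Forest-based / tree-based (weak).**  A *support forest* is read as
  a spanning union of rooted trees (in-degree ≤ 1 within the forest)
  whose outdegree-0 vertices are exactly the taxa and whose non-forest
  arcs join different trees.  The alternative reading that only forbids
  underlying cycles admits forests with two arcs into one reticulation;
  under it, instances exist that are "forest-based" yet admit no valid
  path collection, so the rooted-tree reading is the one under which
  the path-partition theory is coherent — and any such forest thins to
  one outgoing arc per non-taxon vertex with pairwise distinct heads,
  i.e. a system of vertex-disjoint directed paths, which is exactly
  what the exact search enumerates.  At the semi-directed level the
  equivalent object is a collection of vertex-disjoint semi-directed
  paths, one per taxon, each running from a non-taxon *handy vertex*
  (or trivially sitting on a taxon), such that each *cross component*
  (maximal edge-connected piece joining different paths) has at most
  one non-handy vertex (P3), and — for forest-based — any two same-path
  vertices adjacent in `N` are consecutive on their path (P4; only
  forward arc chords can occur, since an edge or backward-arc chord
  would close a semi-directed cycle).  `collection_to_rooting` orients
  paths toward their taxa and cross components away from their
  non-handy centre; a cross component that is a single taxon–taxon edge
  has no orientable centre and receives a fresh subdivision root.
  Production deciders enumerate (leaf-preserving) rootings and run the
  rooted tests; the path-collection search is the independent
  cross-check.

* **HGT-consistent labellings.**  A binary multi-rooted network is
  orchard iff it carries an integer labelling that is weakly increasing
  along arcs, strictly increasing into non-reticulations, gives each
  reticulation exactly one equal-label parent, *and* leaves every
  non-leaf vertex at least one strictly-later child.  The last
  condition is essential: equal-label arcs model instantaneous lateral
  transfers, and deleting them must leave a spanning forest with the
  same leaf set.  Without it, equal-label chains through consecutive
  reticulations (or a vertex donating along all its arcs) admit
  labellings on networks that no cherry sequence dissolves —
  counterexamples at 9–11 vertices are easy to generate.  The search
  exploits that once each reticulation's donor is fixed, feasibility is
  just acyclicity of the donor-contracted strict-constraint digraph, so
  only `∏ d⁻(r)` donor choices are tried.

## A gap in the nice-rooting shortcut

A rooting is *nice* when every root is a non-taxon vertex of `N` or
subdivides an arc whose tail is a taxon.  It is tempting to decide weak
orchardness by testing only nice rootings.  This fails: the fixture
`nice_rooting_gap` (10 vertices, two roots) is weakly orchard — both by
reduction and by brute force over *all* rootings — yet its nice rooting
with roots `{T, p1}` is not orchard.  The mechanism: reducing the
cherry `(x3, x5)` suppresses the degree-2 vertex `T` in `N` (merging
`x5` next to `p2` and eventually enabling new reticulated cherries),
while in the rooting `T` is a root and survives, leaving `x5` one step
too far from the reticulation.  A few percent of generated instances
exhibit the same gap, so the package decides weak orchardness by
reductions (equivalently, brute force over all rootings) and exposes
the nice-rooting comparison only as the diagnostic
`check_nice_rooting_equivalence`; the acceptance report's
`nice_rooting_equivalence_pct` is expected below 100.

Relatedly, a source component consisting entirely of taxa with no
outgoing arcs (e.g. a lone taxon–taxon edge) admits no nice root at
all; `nice_rooting` then falls back to rooting one of its vertices and
the result simply fails the `is_nice_rooting` predicate.

## The synthetic-data generator

`random_multi_rooted_network(n_leaves, n_reticulations, k, seed)` grows
`k` random rooted binary trees by leaf attachment (each tree at least
two leaves, so `n_leaves ≥ 2k`) and adds reticulations one at a time:
two distinct arcs are chosen, the first is subdivided to provide the
donor, the second to provide the recipient (which becomes a
reticulation), and the connecting arc is added.  Placements are
rejected when they would (i) close a directed cycle, (ii) give a
degree-2 root two reticulation children — its deorientation would
retain a degree-2 vertex, which no valid network may contain, (iii)
give a degree-2 root a leaf + reticulation child pair — the
deorientation would contain a pendant degree-1 vertex with only an
outgoing arc, a shape on which the weak-tree-child and orchard-terminal
characterizations provably fail, or (iv) take both arcs from one
degree-2 root, whose suppression would create a parallel arc.  With
`unresolve > 0`, eligible internal arcs are contracted to produce
multifurcations.  `random_msd` returns the semi-deorientation with the
taxon set carried over.

The generator therefore emulates binary-grown reticulate histories
with well-separated roots.  What it does not emulate: pendant
non-taxon lineages, parallel-arc histories, very high reticulation
densities (placement may be rejected as infeasible), or any notion of
branch lengths and real inference noise.  Passing tests show the
characterizations and their oracles agree on this instance family;
they say nothing about degenerate inputs outside it, which the
recognizers still classify correctly but which the class
characterizations partly do not cover (the pendant shapes excluded in
(iii) are the known problematic family).

Test and acceptance problem sizes — networks of ≤ 12–14 vertices, with
500 instances for recognition, 200 for the counting and class-
equivalence suites and 100 for the strong-orchard comparison — were
chosen so that every exhaustive oracle (all rootings, all cycles, all
subsets, all orientations) runs in milliseconds per instance while the
instance family still contains all the phenomena of interest
(multi-rooted inputs, taxa turned roots, weak-but-not-strong examples
of every class).

## Limitations

* Forest-based membership, path-collection search, cycle enumeration,
  the ∧-path oracle and the strong-orchard exploration are exponential
  by design (no polynomial algorithms are known for the hard ones);
  each carries an explicit size guard and raises rather than running
  unbounded.  Practical scope is roughly 15–20 vertices.
* Strong-orchard via sequences requires a semi-directed input; for
  multi-rooted inputs only the brute-force route is offered and is
  flagged experimental.
* The `fig*` fixtures are caption-consistent reconstructions of
  published illustrative examples, not verbatim transcriptions; every
  fact asserted about them is re-derived by the brute-force oracles in
  the test suite.
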