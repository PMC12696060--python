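# sdnet — semi-directed phylogenetic networks: recognition and classification

Semi-directed networks have become a standard object in phylogenetics:
they are what remains of a rooted phylogenetic network when the root
location cannot be inferred from data.  Formally, starting from a rooted
network (a DAG whose leaves are the taxa `X` and whose indegree-≥2
vertices — *reticulations* — model hybridization or gene flow), every
arc that does not enter a reticulation is replaced by an undirected
edge, and the degree-2 vertex left behind by the root is suppressed.
The result is a *mixed graph* `N = (V, E, A)`: undirected edges where
direction is unidentifiable, directed arcs into reticulations where it
is.  Allowing several roots gives *multi-rooted* networks and their
*multi-semi-directed* deorientations.

This definition is implicit — a mixed graph is a semi-directed network
if *some* rooted network deorients to it — which raises two concrete
questions this package answers:

1. **Recognition.**  Is a given mixed graph a (multi-)semi-directed
   network at all, and what are its possible rootings?  `sdnet`
   implements the explicit characterization (no degree-2 vertices and
   `d⁻(v) ∈ {0, d(v)−1}`; no semi-directed cycle; no edge-path joining
   two reticulations), a constructive near-linear recognizer (root one
   vertex per source component, orient, verify), and the exact
   description of feasible root locations: one choice per source
   component among its vertices, its edges, and its outgoing arcs.
   The number of roots is forced: every rooting of `N = (V, E, A)` has
   `|V| − |R| − |E|` roots, where `R` is the reticulation set, and the
   reticulation number satisfies `|A| − |R| = |E| + |A| − |V| + k`.

2. **Classification.**  Does `N` have a rooting in a well-known class
   (*weakly* tree-child / tree-based / orchard / forest-based), or are
   *all* of its rootings in the class (*strongly*)?  The deciders use
   the structural characterizations — omnians (`d⁺ ≥ 1`, `dᵉ ≤ 1`) for
   tree-child, Hall's condition on an omnian/reticulation bipartite
   graph for strongly tree-based, cherry-picking sequences for orchard,
   and vertex-disjoint semi-directed path collections for tree-based
   and forest-based — each cross-validated in the test suite against
   brute force over all rootings.

Everything operates on a small immutable `MixedGraph` container; random
multi-rooted networks and their deorientations are generated by a
seeded simulator, so the package is fully self-contained.

## Worked example

The bundled fixture `F3` is the smallest interesting semi-directed
network: taxa `{a, b, c}`, a chain `a–u–v–b` of edges, and a
reticulation `r` with parents `u` and `v` and pendant leaf `c`:

```
taxa a b c
edge a u
edge b v
edge c r
edge u v
arc u r
arc v r
```

```
$ sdnet check f3.sdn --semi-directed
{"conditions": {"I": {"holds": true, "witness": null},
                "II": {"holds": true, "witness": null},
                "III": {"holds": true, "witness": null}},
 "k": 1, "property": "semi-directed", "reticulation_number": 1,
 "verdict": true}
```

All three recognition conditions hold, so `F3` is semi-directed with a
single root (`k = 1`) and reticulation number 1.  Its nine rootings
(four vertices + three edges + two outgoing arcs of the unique source
component) can be listed with `sdnet rootings f3.sdn`, and class
membership queried directly:

```
$ sdnet classify f3.sdn --property orchard --mode weak
{"k": 1, "mode": "weak", "property": "orchard", "reticulation_number": 1,
 "verdict": true, "witness": [["a", "c"], ["a", "b"]]}
```

The witness is a cherry-picking sequence: `(a, c)` is a reticulated
cherry (deleting the arc `(u, r)` and suppressing dissolves the
reticulation), after which `(a, b)` is an ordinary cherry and the graph
collapses to a single edge on taxa — so some rooting of `F3` is an
orchard network.  In fact all of them are: `sdnet classify f3.sdn
--property orchard --mode strong` also exits with verdict `true`.

The same queries are available in Python:

```python
>>> import sdnet as S
>>> n = S.fixtures()["F3"]
>>> S.is_semi_directed(n), S.root_count(n), S.reticulation_number(n)
(True, 1, 1)
>>> S.is_strongly_tree_child(n), S.is_weakly_forest_based(n)
(True, True)
```

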