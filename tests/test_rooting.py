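"""Root configurations and rootings: feasibility, construction,
enumeration, and nice rootings."""

import itertools

import pytest

from sdnet.core import GraphError, semi_deorient
from sdnet.recognition import root_count
from sdnet.rooted import is_multi_rooted_network
from sdnet.rooting import (
    RootConfiguration,
    apply_root_configuration,
    enumerate_nice_rootings,
    enumerate_root_configurations,
    enumerate_rootings,
    is_nice_rooting,
    is_rooting_of,
    is_valid_root_configuration,
    nice_rooting,
)

from conftest import random_network_stream


def test_configuration_validity_on_f3(fx):
    f3 = fx["F3"]
    assert is_valid_root_configuration(f3, RootConfiguration.of(vertices=["u"]))
    assert not is_valid_root_configuration(f3, RootConfiguration.of(vertices=["r"]))
    assert not is_valid_root_configuration(f3, RootConfiguration.of(vertices=["a", "b"]))
    assert is_valid_root_configuration(f3, RootConfiguration.of(arcs=[("u", "r")]))
    assert not is_valid_root_configuration(f3, RootConfiguration.of())
    with pytest.raises(GraphError):
        is_valid_root_configuration(f3, RootConfiguration.of(vertices=["zz"]))


def test_apply_configuration_examples(fx):
    f3 = fx["F3"]
    r = apply_root_configuration(f3, RootConfiguration.of(vertices=["a"]))
    assert r.network.arcs == frozenset(
        {("a", "u"), ("u", "v"), ("u", "r"), ("v", "b"), ("v", "r"), ("r", "c")}
    )
    r = apply_root_configuration(f3, RootConfiguration.of(arcs=[("u", "r")]))
    (w,) = r.subdivision_map
    assert r.subdivision_map[w] == ("u", "r")
    assert {(w, "u"), (w, "r"), ("u", "a"), ("u", "v"),
            ("v", "b"), ("v", "r"), ("r", "c")} == set(r.network.arcs)
    # rooting F1 on its edge: the fresh root disappears on deorientation
    f1 = fx["F1"]
    r = apply_root_configuration(f1, RootConfiguration.of(edges=[("x", "y")]))
    assert semi_deorient(r.network) == f1


def test_enumeration_counts(fx):
    assert len(list(enumerate_root_configurations(fx["F3"]))) == 9
    assert len(list(enumerate_root_configurations(fx["F3"], leaf_preserving=True))) == 7
    assert len(list(enumerate_root_configurations(fx["F1"]))) == 3
    rootings = list(enumerate_rootings(fx["F3"]))
    assert len(rootings) == 9
    assert all(len(r.roots()) == 1 for r in rootings)


def test_every_enumerated_rooting_round_trips():
    for n in random_network_stream(13, 25):
        for r in enumerate_rootings(n):
            assert is_multi_rooted_network(r.network)
            assert semi_deorient(r.network) == n
            assert is_rooting_of(r.network, n)


def test_validity_matches_brute_force_orientation_search():
    """A configuration is feasible iff apply succeeds, iff some
    orientation of the network realizes exactly that root set."""
    for n in random_network_stream(17, 12, max_vertices=9):
        vertices = sorted(n.vertices)
        # all single- and double-vertex configurations
        cfgs = [RootConfiguration.of(vertices=[v]) for v in vertices]
        cfgs += [RootConfiguration.of(vertices=list(p))
                 for p in itertools.combinations(vertices, 2)]
        for cfg in cfgs:
            valid = is_valid_root_configuration(n, cfg)
            try:
                rooting = apply_root_configuration(n, cfg)
                applied = True
                assert rooting.roots() == set(cfg.root_vertices)
            except GraphError:
                applied = False
            assert valid == applied
            # brute force: try every orientation of the edges
            edges = sorted(n.edges, key=sorted)
            found = False
            for bits in itertools.product((0, 1), repeat=len(edges)):
                arcs = set(n.arcs)
                for e, b in zip(edges, bits):
                    u, v = sorted(e)
                    arcs.add((u, v) if b else (v, u))
                cand = n.replace(edges=frozenset(), arcs=frozenset(arcs))
                if is_rooting_of(cand, n) and cand.roots() == set(cfg.root_vertices):
                    found = True
                    break
            assert found == valid


def test_nice_rooting_properties(fx):
    r = nice_rooting(fx["F3"])
    assert is_nice_rooting(r)
    assert r.roots() == {"u"}
    r = nice_rooting(fx["F7"])
    assert is_nice_rooting(r)
    assert semi_deorient(r.network) == fx["F7"]
    for n in random_network_stream(29, 20):
        r = nice_rooting(n)
        assert is_rooting_of(r.network, n)
        assert len(r.roots()) == root_count(n)


def test_nice_rooting_degenerate_single_edge(fx):
    # a single taxon-taxon edge has no non-taxon vertex and no arc: the
    # fallback roots a taxon and the result is flagged as not nice
    r = nice_rooting(fx["F1"])
    assert is_rooting_of(r.network, fx["F1"])
    assert not is_nice_rooting(r)


def test_enumerate_nice_rootings_are_nice_when_possible(fx):
    for r in enumerate_nice_rootings(fx["F3"]):
        assert is_nice_rooting(r)
    for r in enumerate_nice_rootings(fx["F7"]):
        assert is_nice_rooting(r)
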