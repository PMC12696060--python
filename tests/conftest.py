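import random

import pytest

from sdnet.core import GraphError, build_graph
from sdnet.data_io import random_msd, random_multi_rooted_network
from sdnet.fixtures import fixtures as _fixtures


@pytest.fixture(scope="session")
def fx():
    return _fixtures()


def random_network_stream(seed, count, max_vertices=12, k_choices=(1, 1, 1, 2, 2, 3),
                          max_extra_leaves=3, max_rets=3, unresolve_choices=(0.0,)):
    """Yield up to *count* random multi-semi-directed networks."""
    rng = random.Random(seed)
    made = 0
    attempts = 0
    while made < count and attempts < 50 * count:
        attempts += 1
        k = rng.choice(list(k_choices))
        nl = rng.randint(2 * k, 2 * k + max_extra_leaves)
        nr = rng.randint(0, max_rets)
        unr = rng.choice(list(unresolve_choices))
        try:
            n = random_msd(nl, nr, k, rng=rng, unresolve=unr)
        except GraphError:
            continue
        if len(n.vertices) > max_vertices:
            continue
        made += 1
        yield n


def random_rooted_stream(seed, count, max_vertices=14, **kw):
    rng = random.Random(seed)
    made = 0
    attempts = 0
    while made < count and attempts < 50 * count:
        attempts += 1
        k = rng.choice([1, 1, 2, 3])
        nl = rng.randint(2 * k, 2 * k + 3)
        nr = rng.randint(0, 3)
        try:
            d = random_multi_rooted_network(nl, nr, k, rng=rng, **kw)
        except GraphError:
            continue
        if len(d.vertices) > max_vertices:
            continue
        made += 1
        yield d


def random_mixed_graph(rng, n_vertices):
    """An arbitrary (often invalid as a network) mixed graph: random
    edges and arcs avoiding parallel/antiparallel pairs."""
    verts = [f"n{i}" for i in range(n_vertices)]
    edges, arcs = [], []
    used = set()
    for _ in range(rng.randint(0, 2 * n_vertices)):
        u, v = rng.sample(verts, 2)
        key = frozenset((u, v))
        if key in used:
            continue
        used.add(key)
        if rng.random() < 0.5:
            edges.append((u, v))
        else:
            arcs.append((u, v))
    return build_graph(verts, edges, arcs, taxa=[])
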