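import itertools
from math import comb

import networkx as nx
import numpy as np
import pytest

from netprio.ppin_io import InteractionNetwork, SeedList


def net_from_edges(edges, label="test"):
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractionNetwork(graph=g, source_label=label)


def random_connected_graph(rng: np.random.Generator, max_n: int = 8):
    """Small random connected graph for oracle comparisons."""
    n = int(rng.integers(2, max_n + 1))
    p = float(rng.uniform(0.25, 0.9))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
    comp = max(nx.connected_components(g), key=len) if g.number_of_nodes() else set()
    if len(comp) < 2:
        g = nx.path_graph(2)
        comp = set(g.nodes)
    sub = g.subgraph(comp).copy()
    return net_from_edges([(f"N{u}", f"N{v}") for u, v in sub.edges])


def hypergeom_tail_enumerated(n_a, n_b, k, universe):
    """P(overlap >= k) by exhaustive enumeration of draws (small universes only)."""
    pool = list(range(universe))
    successes = set(pool[:n_b])
    total = comb(universe, n_a)
    hits = sum(
        1
        for draw in itertools.combinations(pool, n_a)
        if len(successes.intersection(draw)) >= k
    )
    return hits / total


def bh_reference(p_values):
    """Independent step-up reference (statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(list(p_values), method="fdr_bh")[1]


@pytest.fixture
def path_net():
    return net_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_net():
    return net_from_edges([("X", leaf) for leaf in ("L1", "L2", "L3", "L4")])


@pytest.fixture
def cycle_net():
    return net_from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


@pytest.fixture
def seed_list():
    def make(*symbols, provenance="test-seeds"):
        return SeedList(symbols=frozenset(symbols), provenance=provenance)

    return make
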