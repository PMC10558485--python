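import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helpers

import hypercores as hc


@pytest.fixture
def single_triangle():
    """One hyperedge {a, b, c}."""
    return hc.Hypergraph([{"a", "b", "c"}])


@pytest.fixture
def toy():
    return hc.toy_hypergraph()


@pytest.fixture
def planted():
    """Planted (3, 3)-hyper-core on 12 nodes with a 14-node periphery."""
    spec = hc.FixtureSpec(n_nodes=26, seed=42,
                          planted=hc.PlantedCoreSpec(n_core=12, k_core=3,
                                                     m_core=3))
    return hc.planted_core_hypergraph(spec)


def random_suite(n_graphs, seed0=0, n_max=8, e_max=12):
    """Small random hypergraphs with mixed sizes for oracle comparisons."""
    import numpy as np
    graphs = []
    rng = np.random.default_rng(seed0)
    while len(graphs) < n_graphs:
        n = int(rng.integers(4, n_max + 1))
        counts = {}
        budget = int(rng.integers(2, e_max + 1))
        for m in (2, 3, 4):
            if m > n:
                continue
            from math import comb
            c = int(rng.integers(0, min(budget, comb(n, m)) + 1))
            counts[m] = c
            budget -= c
            if budget <= 0:
                break
        if sum(counts.values()) == 0:
            counts[2] = 1
        spec = hc.FixtureSpec(n_nodes=n, size_counts=counts,
                              seed=int(rng.integers(2**31)))
        graphs.append(hc.random_hypergraph(spec))
    return graphs


@pytest.fixture(scope="session")
def small_random_graphs():
    return random_suite(40, seed0=7)
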