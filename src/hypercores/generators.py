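"""Synthetic hypergraph generators: random, planted-core, and a worked toy.

These make every analysis and every stochastic process testable without any
external data: uniformly random hypergraphs with a prescribed hyperedge-size
histogram, hypergraphs with a planted densely hyper-connected core plus a
sparse pairwise periphery, and a small hand-built hypergraph whose full
decomposition exercises the recursive-removal subtleties (hyperedge
downgrading and deduplication).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np

from .hypergraph import Hypergraph


@dataclass(frozen=True)
class PlantedCoreSpec:
    """A planted (k_core, m_core)-hyper-core on n_core nodes."""

    n_core: int
    k_core: int
    m_core: int

    def __post_init__(self):
        if self.m_core > self.n_core:
            raise ValueError("m_core cannot exceed n_core")
        if self.m_core < 2 or self.k_core < 1:
            raise ValueError("need m_core >= 2 and k_core >= 1")
        if self.k_core > comb(self.n_core - 1, self.m_core - 1):
            raise ValueError("k_core infeasible: not enough distinct "
                             "hyperedges through a node")


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a synthetic hypergraph.

    ``size_counts`` maps hyperedge size m to the requested number of distinct
    hyperedges of that size.  ``mean_d2`` optionally sets a target mean
    pairwise degree, translated into a size-2 edge count N * mean_d2 / 2 when
    no explicit size-2 count is given.
    """

    n_nodes: int
    size_counts: dict[int, int] | None = None
    mean_d2: float | None = None
    planted: PlantedCoreSpec | None = None
    seed: object = None

    def resolved_counts(self) -> dict[int, int]:
        counts = dict(self.size_counts or {})
        if self.mean_d2 is not None and 2 not in counts:
            counts[2] = round(self.n_nodes * self.mean_d2 / 2)
        for m, c in counts.items():
            if m < 2 or c < 0:
                raise ValueError(f"bad size count ({m}: {c})")
            if c > comb(self.n_nodes, m):
                raise ValueError(
                    f"{c} distinct hyperedges of size {m} requested but only "
                    f"C({self.n_nodes},{m}) = {comb(self.n_nodes, m)} exist")
        return counts


def random_hypergraph(spec: FixtureSpec) -> Hypergraph:
    """Uniformly random distinct m-subsets for each requested size.

    Rejection sampling enforces distinctness; feasibility (count <= C(N, m))
    is validated up front.
    """
    counts = spec.resolved_counts()
    rng = np.random.default_rng(spec.seed)
    edges: set[frozenset] = set()
    for m in sorted(counts):
        want = counts[m]
        placed = 0
        while placed < want:
            e = frozenset(int(v) for v in
                          rng.choice(spec.n_nodes, size=m, replace=False))
            if e not in edges:
                edges.add(e)
                placed += 1
    return Hypergraph(edges, nodes=range(spec.n_nodes))


def planted_core_hypergraph(spec: FixtureSpec) -> tuple[Hypergraph, set]:
    """Hypergraph with a planted hyper-core plus a pairwise periphery.

    Distinct size-``m_core`` hyperedges are placed inside the first
    ``n_core`` nodes until every planted node lies in at least ``k_core`` of
    them, so the planted set is contained in the (k_core, m_core)-hyper-core.
    Every remaining node is attached to the core by a single size-2 edge.
    Returns ``(hypergraph, planted node set)``.
    """
    if spec.planted is None:
        raise ValueError("spec.planted is required")
    ps = spec.planted
    if ps.n_core > spec.n_nodes:
        raise ValueError("planted core larger than the node set")
    rng = np.random.default_rng(spec.seed)
    core = list(range(ps.n_core))
    edges: set[frozenset] = set()
    coverage = np.zeros(ps.n_core, dtype=int)
    guard = 0
    while coverage.min() < ps.k_core:
        guard += 1
        if guard > 100_000:
            raise RuntimeError("planted-core construction failed to converge")
        u = int(np.argmin(coverage))
        others = rng.choice(ps.n_core - 1, size=ps.m_core - 1, replace=False)
        e = frozenset([u] + [int(o) if o < u else int(o) + 1 for o in others])
        if e not in edges:
            edges.add(e)
            for v in e:
                coverage[v] += 1
    for v in range(ps.n_core, spec.n_nodes):
        edges.add(frozenset({v, int(rng.integers(ps.n_core))}))
    extra = spec.resolved_counts()
    for m in sorted(extra):
        want = extra[m]
        placed = 0
        while placed < want:
            e = frozenset(int(v) for v in
                          rng.choice(spec.n_nodes, size=m, replace=False))
            if e not in edges:
                edges.add(e)
                placed += 1
    H = Hypergraph(edges, nodes=range(spec.n_nodes))
    return H, set(core)


def toy_hypergraph() -> Hypergraph:
    """A hand-built 14-node hypergraph with a rich, known decomposition.

    Contains a dense 3-uniform cluster, a lone triangle hyperedge, a pair of
    size-3 hyperedges that survive the (1, 3)-core but collapse under the
    (2, 3) peeling (so node 8 has D_3 = 2 yet C_3 = 1), and a pairwise
    triangle that enters the (2, 2)-core only.  Its full hyper-core profile
    is pre-computed by the exhaustive subset oracle and shipped with the
    test suite.
    """
    triples = [{1, 2, 3}, {1, 2, 4}, {1, 3, 4}, {2, 3, 4},
               {5, 6, 7}, {8, 9, 10}, {8, 9, 11}]
    pairs = [{12, 13}, {12, 1}, {13, 1}, {4, 5}, {7, 8}, {2, 14}]
    return Hypergraph(triples + pairs)
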