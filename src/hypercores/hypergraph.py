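"""Hypergraph container and the weighted pairwise projection.

A hypergraph is a set of nodes together with a *set* of hyperedges, where a
hyperedge is a set of at least two distinct nodes representing one group
interaction.  Set semantics are enforced throughout: duplicate hyperedges are
merged and singleton hyperedges are dropped on construction (the decomposition
machinery starts at group size m = 2).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

Node = Hashable


def _sort_key(label: Node):
    # stable ordering for mixed label types
    return (type(label).__name__, repr(label))


class Hypergraph:
    """Immutable hypergraph with deduplicated hyperedges of size >= 2.

    Parameters
    ----------
    hyperedges :
        Iterable of node collections.  Each is converted to a ``frozenset``;
        duplicates are merged and singletons dropped (counts are kept in
        :attr:`n_duplicate_edges` and :attr:`n_dropped_singletons`).
    nodes :
        Optional extra node labels.  Nodes appearing in no hyperedge are kept
        so that score tables have a stable schema.
    """

    def __init__(self, hyperedges: Iterable[Iterable[Node]],
                 nodes: Iterable[Node] | None = None):
        seen: set[frozenset] = set()
        n_dup = 0
        n_singleton = 0
        for raw in hyperedges:
            e = frozenset(raw)
            if len(e) < 2:
                n_singleton += 1
                continue
            if e in seen:
                n_dup += 1
            else:
                seen.add(e)
        self._edges: frozenset[frozenset] = frozenset(seen)
        self.n_duplicate_edges = n_dup
        self.n_dropped_singletons = n_singleton

        node_set = {v for e in self._edges for v in e}
        if nodes is not None:
            node_set.update(nodes)
        self._nodes: tuple = tuple(sorted(node_set, key=_sort_key))
        self._index: dict = {v: i for i, v in enumerate(self._nodes)}
        # stable edge order: by sorted member indices
        self._edge_list: list[frozenset] = sorted(
            self._edges, key=lambda e: sorted(self._index[v] for v in e))

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple:
        return self._nodes

    @property
    def hyperedges(self) -> frozenset[frozenset]:
        return self._edges

    @property
    def edge_list(self) -> list[frozenset]:
        """Hyperedges in a deterministic order."""
        return list(self._edge_list)

    @property
    def N(self) -> int:
        return len(self._nodes)

    @property
    def M(self) -> int:
        """Largest hyperedge size (0 for an edgeless hypergraph)."""
        return max((len(e) for e in self._edges), default=0)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def index_of(self, node: Node) -> int:
        return self._index[node]

    def node_index(self) -> Mapping[Node, int]:
        """Stable label -> dense integer index map."""
        return dict(self._index)

    # -- degrees and size statistics ---------------------------------------
    def degree(self, node: Node, m: int) -> int:
        """d_m(i): number of hyperedges of size exactly ``m`` containing node."""
        return sum(1 for e in self._edges if len(e) == m and node in e)

    def degree_vector(self, node: Node) -> dict[int, int]:
        d: Counter = Counter()
        for e in self._edges:
            if node in e:
                d[len(e)] += 1
        return {m: d.get(m, 0) for m in range(2, self.M + 1)}

    def degree_at_least(self, node: Node, m: int) -> int:
        """D_m(i): number of hyperedges of size >= ``m`` containing node."""
        return sum(1 for e in self._edges if len(e) >= m and node in e)

    def size_counts(self) -> dict[int, int]:
        c = Counter(len(e) for e in self._edges)
        return {m: c.get(m, 0) for m in range(2, self.M + 1)}

    def size_distribution(self) -> dict[int, float]:
        """Psi(m): fraction of hyperedges of size m, for m in [2, M]."""
        counts = self.size_counts()
        total = sum(counts.values())
        if total == 0:
            return {}
        return {m: c / total for m, c in counts.items()}

    def incidence(self) -> sparse.csr_matrix:
        """Sparse |E| x N incidence matrix in the stable edge/node order."""
        rows, cols = [], []
        for r, e in enumerate(self._edge_list):
            for v in e:
                rows.append(r)
                cols.append(self._index[v])
        data = np.ones(len(rows), dtype=np.int64)
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(len(self._edge_list), self.N))

    def edges_as_index_sets(self) -> list[frozenset[int]]:
        """Hyperedges with labels replaced by dense integer indices."""
        return [frozenset(self._index[v] for v in e) for e in self._edge_list]

    # -- dunder -------------------------------------------------------------
    def __eq__(self, other) -> bool:
        if not isinstance(other, Hypergraph):
            return NotImplemented
        return set(self._nodes) == set(other._nodes) and self._edges == other._edges

    def __hash__(self):
        return hash((frozenset(self._nodes), self._edges))

    def __repr__(self) -> str:
        return f"Hypergraph(N={self.N}, |E|={self.n_edges}, M={self.M})"


@dataclass(frozen=True)
class ContactStream:
    """Timestamped pairwise contact events (t, i, j), e.g. face-to-face data.

    ``window`` is the aggregation window length in seconds; the default of
    900 s (15 minutes) is the standard choice for proximity data.
    """

    events: tuple = field(default_factory=tuple)
    window: int = 900

    def __post_init__(self):
        ev = []
        for t, i, j in self.events:
            if i == j:
                raise ValueError(f"self-contact ({i},{j}) at t={t}")
            ev.append((int(t), i, j))
        ev.sort(key=lambda x: (x[0], _sort_key(x[1]), _sort_key(x[2])))
        object.__setattr__(self, "events", tuple(ev))

    @property
    def t0(self) -> int:
        if not self.events:
            raise ValueError("empty contact stream")
        return self.events[0][0]


@dataclass
class WeightedProjection:
    """Weighted pairwise projection of a hypergraph.

    Each hyperedge is expanded into a clique; the weight of edge (i, j) is the
    number of distinct hyperedges containing both endpoints.  Carries the
    s-coreness (strength-based coreness of the weighted graph) and the plain
    k-coreness of the unweighted graph.
    """

    graph: nx.Graph
    strength: dict
    s_coreness: dict
    k_coreness: dict

    def weight(self, i: Node, j: Node) -> int:
        return self.graph[i][j]["weight"]


def _s_core_numbers(G: nx.Graph) -> dict:
    """Strength-based coreness via successive minimum-strength peeling.

    Weights are positive integers, so S(i) is the largest integer s such that
    i survives in the s-core (the maximal subgraph with all strengths >= s).
    """
    C = G.copy()
    S: dict = {}
    strength = {v: sum(d["weight"] for d in C[v].values()) for v in C}
    for v in [v for v in C if strength[v] == 0]:
        S[v] = 0
        C.remove_node(v)
        del strength[v]
    while C.number_of_nodes() > 0:
        t = min(strength.values())
        # everyone present survives the t-core; peel for threshold t+1
        stack = [v for v in C if strength[v] < t + 1]
        while stack:
            v = stack.pop()
            if v not in strength:
                continue
            S[v] = t
            for u in list(C[v]):
                strength[u] -= C[v][u]["weight"]
                if strength[u] < t + 1:
                    stack.append(u)
            C.remove_node(v)
            del strength[v]
    return S


def project_to_weighted_graph(H: Hypergraph) -> WeightedProjection:
    """Clique-expand ``H`` into a weighted graph and compute its corenesses."""
    if H.n_edges == 0 and H.N == 0:
        raise ValueError("cannot project an empty hypergraph")
    G = nx.Graph()
    G.add_nodes_from(H.nodes)
    for e in H.edge_list:
        members = sorted(e, key=_sort_key)
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                if G.has_edge(i, j):
                    G[i][j]["weight"] += 1
                else:
                    G.add_edge(i, j, weight=1)
    strength = {v: sum(d["weight"] for d in G[v].values()) for v in G}
    s_core = _s_core_numbers(G)
    k_core = nx.core_number(G)
    return WeightedProjection(graph=G, strength=strength,
                              s_coreness=s_core, k_coreness=k_core)
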