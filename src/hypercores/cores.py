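"""(k, m)-hyper-core decomposition, shell indices and hypercoreness.

The (k, m)-hyper-core of a hypergraph is the maximum subhypergraph, with
hyperedges of size at least m, in which every node belongs to at least k
distinct hyperedges of size at least m *within the subhypergraph*.  It is
obtained by discarding all hyperedges of size < m and recursively removing
every node with fewer than k remaining hyperedges of size >= m.  Removing a
node shrinks each hyperedge containing it by one member; a shrunk hyperedge
is deleted when it drops below size m or when it coincides with a hyperedge
already present (set semantics among the current, possibly shrunk,
hyperedges).

The m-shell index C_m(i) is the largest k such that node i belongs to the
(k, m)-hyper-core, and k_max^m the largest k with a non-empty core at size m.
The hypercoreness of node i under a non-negative weight function g is

    R_g(i) = sum_{m=2}^{M} g(m) * C_m(i) / k_max^m,

with the convention that a size m with k_max^m = 0 contributes 0.  g = 1
gives the size-independent hypercoreness R (bounded by M - 1); g = Psi, the
empirical hyperedge-size frequency, gives the frequency-based hypercoreness
R_w (bounded by 1).
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import pandas as pd

from .hypergraph import Hypergraph, Node


class _Peeler:
    """Stateful peeling of one size level m, raising k one unit at a time.

    Because the cores are nested in k, the surviving (possibly shrunk)
    subhypergraph at level k is a valid starting point for level k + 1.
    """

    def __init__(self, edges: Iterable[frozenset], m: int):
        self.m = m
        self.store: dict[int, frozenset] = {}
        self.present: set[frozenset] = set()
        self.inc: dict = {}
        self.deg: Counter = Counter()
        kept = sorted({e for e in edges if len(e) >= m},
                      key=lambda e: sorted(map(repr, e)))
        for eid, e in enumerate(kept):
            self.store[eid] = e
            self.present.add(e)
            for v in e:
                self.inc.setdefault(v, set()).add(eid)
                self.deg[v] += 1
        self.alive: set = set(self.deg)

    def raise_to(self, k: int) -> set:
        """Peel until every surviving node has degree >= k; return survivors."""
        queue = deque(sorted((v for v in self.alive if self.deg[v] < k),
                             key=repr))
        queued = set(queue)
        while queue:
            v = queue.popleft()
            queued.discard(v)
            if v not in self.alive:
                continue
            self.alive.discard(v)
            affected: set = set()
            for eid in sorted(self.inc.get(v, ())):
                e = self.store.pop(eid)
                self.present.discard(e)
                for u in e:
                    if u != v:
                        self.inc[u].discard(eid)
                    self.deg[u] -= 1
                    affected.add(u)
                shrunk = e - {v}
                if len(shrunk) >= self.m and shrunk not in self.present:
                    self.store[eid] = shrunk
                    self.present.add(shrunk)
                    for u in shrunk:
                        self.inc[u].add(eid)
                        self.deg[u] += 1
            self.inc.pop(v, None)
            for u in affected:
                if u in self.alive and u not in queued and self.deg[u] < k:
                    queue.append(u)
                    queued.add(u)
        return set(self.alive)


def km_core(H: Hypergraph, k: int, m: int) -> set:
    """Node set of the (k, m)-hyper-core of ``H`` (empty set if none survives)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if m < 2:
        raise ValueError(f"m must be >= 2, got {m}")
    peeler = _Peeler(H.hyperedges, m)
    return peeler.raise_to(k)


@dataclass
class HypercoreProfile:
    """Full (k, m)-hyper-core structure of a hypergraph.

    Stores the shell indices C_m(i); every core node set is recovered as
    ``{i : C_m(i) >= k}``, relying on the nesting of cores in k.
    """

    nodes: tuple
    shell_index: dict[int, dict[Node, int]]   # m -> node -> C_m(i)
    kmax: dict[int, int]                      # m -> k_max^m
    size_distribution: dict[int, float]       # Psi(m), from the source data
    N: int = field(init=False)

    def __post_init__(self):
        self.N = len(self.nodes)

    @property
    def M(self) -> int:
        return max(self.shell_index, default=1)

    def core(self, k: int, m: int) -> set:
        """Node set of the (k, m)-hyper-core."""
        if k < 1 or m < 2:
            raise ValueError("need k >= 1 and m >= 2")
        cm = self.shell_index.get(m, {})
        return {v for v, c in cm.items() if c >= k}

    def n(self, k: int, m: int) -> float:
        """Relative core size n_(k,m) = |core(k, m)| / N."""
        return len(self.core(k, m)) / self.N

    def shell(self, k: int, m: int) -> set:
        """The (k, m)-shell: nodes with C_m(i) exactly k."""
        return {v for v, c in self.shell_index.get(m, {}).items() if c == k}

    def shell_indices(self, m: int) -> dict[Node, int]:
        cm = self.shell_index.get(m, {})
        return {v: cm.get(v, 0) for v in self.nodes}

    def core_sizes(self) -> pd.DataFrame:
        """Tidy table of (m, k, core_size, n_km) over all non-trivial cells."""
        rows = []
        for m in sorted(self.shell_index):
            for k in range(1, self.kmax.get(m, 0) + 1):
                size = len(self.core(k, m))
                rows.append((m, k, size, size / self.N))
        return pd.DataFrame(rows, columns=["m", "k", "core_size", "n_km"])

    def shell_table(self) -> pd.DataFrame:
        """Per-node table of shell indices C_2 .. C_M."""
        data = {"node": list(self.nodes)}
        for m in sorted(self.shell_index):
            data[f"C_{m}"] = [self.shell_index[m].get(v, 0) for v in self.nodes]
        return pd.DataFrame(data)


def decompose(H: Hypergraph) -> HypercoreProfile:
    """Compute the full hyper-core profile of ``H``.

    For each size level m in [2, M], k is raised one unit at a time on the
    surviving subhypergraph; nodes dropped while raising k to k + 1 get shell
    index C_m = k.
    """
    if H.n_edges == 0:
        raise ValueError("cannot decompose a hypergraph with no hyperedges")
    shell_index: dict[int, dict[Node, int]] = {}
    kmax: dict[int, int] = {}
    for m in range(2, H.M + 1):
        peeler = _Peeler(H.hyperedges, m)
        cm: dict[Node, int] = {v: 0 for v in H.nodes}
        k = 1
        current = peeler.raise_to(1)
        while current:
            for v in current:
                cm[v] = k
            k += 1
            current = peeler.raise_to(k)
        shell_index[m] = cm
        kmax[m] = k - 1
    return HypercoreProfile(nodes=H.nodes, shell_index=shell_index,
                            kmax=kmax,
                            size_distribution=H.size_distribution())


@dataclass
class HypercorenessScores:
    """Per-node hypercoreness R_g for a tabulated weight function g."""

    g: dict[int, float]
    scores: dict[Node, float]
    name: str = "R_g"

    def __getitem__(self, node: Node) -> float:
        return self.scores[node]

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, name=self.name)


def hypercoreness(profile: HypercoreProfile,
                  g: Mapping[int, float] | Callable[[int], float],
                  name: str = "R_g") -> HypercorenessScores:
    """R_g(i) = sum_m g(m) C_m(i)/k_max^m; sizes with k_max^m = 0 contribute 0."""
    ms = sorted(profile.shell_index)
    if callable(g):
        g_tab = {m: float(g(m)) for m in ms}
    else:
        g_tab = {m: float(g.get(m, 0.0)) for m in ms}
    if any(v < 0 for v in g_tab.values()):
        raise ValueError("weight function g must be non-negative")
    scores: dict[Node, float] = {}
    for v in profile.nodes:
        total = 0.0
        for m in ms:
            km = profile.kmax.get(m, 0)
            if km > 0:
                total += g_tab[m] * profile.shell_index[m].get(v, 0) / km
        scores[v] = total
    return HypercorenessScores(g=g_tab, scores=scores, name=name)


def size_independent_hypercoreness(profile: HypercoreProfile) -> HypercorenessScores:
    """R: hypercoreness with g(m) = 1, weighing all group sizes equally."""
    return hypercoreness(profile, lambda m: 1.0, name="R")


def frequency_based_hypercoreness(profile: HypercoreProfile) -> HypercorenessScores:
    """R_w: hypercoreness weighted by the hyperedge-size frequency Psi(m)."""
    psi = profile.size_distribution
    return hypercoreness(profile, {m: psi.get(m, 0.0) for m in profile.shell_index},
                         name="R_w")
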