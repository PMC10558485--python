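"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's peeling/simulation code paths:
hyper-cores are found by exhaustive search over node subsets, s-cores by
exhaustive subset search on the projection, maximal cliques by subset
maximality checks, and the small Markov chains by transition-matrix powering.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


# -- exhaustive (k, m)-hyper-core ------------------------------------------

def km_core_bruteforce(nodes, hyperedges, k, m):
    """Union of all node subsets A satisfying the defining property.

    A is valid when, with S = deduplicated {e & A : |e & A| >= m}, every node
    of A lies in at least k members of S.  Validity is closed under union, so
    the union of valid subsets is the maximum subhypergraph's node set.
    """
    nodes = sorted(nodes, key=repr)
    pos = {v: i for i, v in enumerate(nodes)}
    masks = [sum(1 << pos[v] for v in e) for e in hyperedges]
    n = len(nodes)
    best = 0
    for a_mask in range(1, 1 << n):
        induced = {em & a_mask for em in masks}
        induced = [s for s in induced if bin(s).count("1") >= m]
        ok = True
        probe = a_mask
        while probe:
            bit = probe & (-probe)
            if sum(1 for s in induced if s & bit) < k:
                ok = False
                break
            probe ^= bit
        if ok:
            best |= a_mask
    return {nodes[i] for i in range(n) if best & (1 << i)}


def decompose_bruteforce(nodes, hyperedges, max_m=None):
    """Full profile {(m, k): core node set} via the exhaustive oracle."""
    M = max((len(e) for e in hyperedges), default=1)
    if max_m is not None:
        M = min(M, max_m)
    out = {}
    for m in range(2, M + 1):
        k = 1
        while True:
            core = km_core_bruteforce(nodes, hyperedges, k, m)
            if not core:
                break
            out[(m, k)] = core
            k += 1
    return out


# -- exhaustive s-core on a weighted graph ---------------------------------

def s_coreness_bruteforce(G):
    """S(i) per node via exhaustive search for maximal min-strength subgraphs."""
    nodes = sorted(G.nodes, key=repr)
    S = {v: 0 for v in nodes}
    s = 1
    while True:
        best = set()
        for r in range(1, len(nodes) + 1):
            for sub in itertools.combinations(nodes, r):
                sub = set(sub)
                ok = all(
                    sum(G[v][u]["weight"] for u in G[v] if u in sub) >= s
                    for v in sub)
                if ok:
                    best |= sub
        if not best:
            break
        for v in best:
            S[v] = s
        s += 1
    return S


# -- exhaustive maximal cliques --------------------------------------------

def maximal_cliques_bruteforce(edges):
    """All subset-maximal cliques (size >= 2) of the graph given by edges."""
    adj = {}
    for i, j in edges:
        adj.setdefault(i, set()).add(j)
        adj.setdefault(j, set()).add(i)
    nodes = sorted(adj, key=repr)
    cliques = []
    for r in range(2, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(b in adj[a] for a, b in itertools.combinations(sub, 2)):
                cliques.append(frozenset(sub))
    return {c for c in cliques
            if not any(c < d for d in cliques if d != c)}


# -- exact two-node SIS chain ----------------------------------------------

def sis_pair_expected_tau(lam, mu, burn_in, T, seed_first=0):
    """E[tau(a)/T], E[tau(b)/T] for SIS on one edge {a, b}, nu = 1.

    Synchronous update on start-of-step states; conditioned on the run not
    hitting extinction (no infectious node) before the window ends.  States:
    0 = SS (absorbing), 1 = IS, 2 = SI, 3 = II.
    """
    q = 1.0 - np.exp(-lam)
    P = np.zeros((4, 4))
    P[0, 0] = 1.0
    # from IS: a recovers w.p. mu; b infected w.p. q (a infectious at start)
    P[1, 0] = mu * (1 - q)
    P[1, 1] = (1 - mu) * (1 - q)
    P[1, 2] = mu * q
    P[1, 3] = (1 - mu) * q
    # from SI symmetric
    P[2, 0] = mu * (1 - q)
    P[2, 2] = (1 - mu) * (1 - q)
    P[2, 1] = mu * q
    P[2, 3] = (1 - mu) * q
    # from II: each recovers independently w.p. mu (no reinfection same step)
    P[3, 0] = mu * mu
    P[3, 1] = mu * (1 - mu)      # b recovers -> IS means a infectious
    P[3, 2] = (1 - mu) * mu
    P[3, 3] = (1 - mu) * (1 - mu)

    Q = P[1:, 1:]  # transient part (extinction = absorption at SS)
    total = burn_in + T
    alpha0 = np.zeros(3)
    alpha0[seed_first] = 1.0  # seed = node a infectious
    # forward sub-probabilities alpha_t (not renormalized: path survives)
    alphas = [alpha0]
    for _ in range(total):
        alphas.append(alphas[-1] @ Q)
    # survival weights from step t to the end
    ones = np.ones(3)
    weights = [ones]
    for _ in range(total):
        weights.append(Q @ weights[-1])
    weights.reverse()
    Zsurv = alphas[0] @ weights[0]
    a_inf = np.array([1.0, 0.0, 1.0])  # states IS, SI, II: a infectious
    b_inf = np.array([0.0, 1.0, 1.0])
    ea = eb = 0.0
    for t in range(burn_in + 1, total + 1):
        cond = alphas[t] * weights[t] / Zsurv
        ea += cond @ a_inf
        eb += cond @ b_inf
    return ea / T, eb / T, Zsurv


# -- exact two-node committed naming-game chain ----------------------------

def ng_pair_absorption_time():
    """Mean steps to absorption for edge {a, b}, a committed, beta=1, union.

    b's dictionary walks {B} -> {A,B} -> {A}; returns the exact expected
    absorption time from {B} by solving the 3-state chain.
    """
    # from {B}: speaker a (prob 1/2) says A, b adds it -> {A,B};
    #           speaker b says B, committed a never updates -> stay
    # from {A,B}: speaker a -> agreement -> {A} (1/2);
    #             speaker b says A (1/4) -> agreement -> {A}; says B (1/4) stay
    P = np.array([
        [0.5, 0.5, 0.0],
        [0.0, 0.25, 0.75],
        [0.0, 0.0, 1.0],
    ])
    Q = P[:2, :2]
    t = np.linalg.solve(np.eye(2) - Q, np.ones(2))
    return t[0]


# -- misc --------------------------------------------------------------------

def degree_vector_tally(hyperedges):
    """Independent degree-vector tally: node -> Counter(size -> count)."""
    out = {}
    for e in hyperedges:
        for v in e:
            out.setdefault(v, Counter())[len(e)] += 1
    return out
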