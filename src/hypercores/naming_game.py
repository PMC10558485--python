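"""Higher-order naming game with committed minorities.

Two names, A and B, compete on a hypergraph.  Every node holds a dictionary
that is a non-empty subset of {A, B}; a committed minority of N_p nodes is
pinned to {A} (its dictionary is never updated), all others start at {B}.
Per time step a hyperedge is chosen uniformly at random, a speaker is chosen
uniformly within it and utters a uniformly random name from its dictionary.
Agreement is *possible* under the chosen rule — union: at least one listener
holds the name; unanimity: every group member holds it — and becomes
*effective* with probability beta, in which case every non-committed group
member's dictionary collapses to the uttered name.  Otherwise every
non-committed listener adds the name to its dictionary.

The order parameter n_A(t) is the fraction of nodes whose dictionary is
exactly {A}, committed included.  A run ends at the absorbing state n_A = 1
or at t_max steps; in the latter case the stationary value n_A* is the mean
of ``n_samples`` values of n_A sampled evenly over the last ``window`` steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Mapping, Sequence

import numpy as np

from .hypergraph import Hypergraph, Node

A, B, AB = 1, 2, 3  # dictionary bit codes: {A}, {B}, {A,B}

STRATEGIES = ("random", "top-R", "top-R_w", "top-s-coreness", "top-k-coreness")


@dataclass
class NGParams:
    """Naming-game run parameters.

    ``n_committed`` is the committed count N_p (fraction p = N_p/N);
    ``window``/``n_samples`` define the stationary average when a run does
    not absorb within ``t_max`` steps.
    """

    beta: float
    n_committed: int
    rule: str = "union"
    strategy: str = "random"
    t_max: int = 500_000
    window: int = 50_000
    n_samples: int = 100
    n_runs: int = 200
    seed: object = None

    def __post_init__(self):
        if not (0 <= self.beta <= 1):
            raise ValueError("beta must be in [0, 1]")
        if self.n_committed < 0:
            raise ValueError("n_committed must be >= 0")
        if self.rule not in ("union", "unanimity"):
            raise ValueError("rule must be 'union' or 'unanimity'")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.window > self.t_max:
            raise ValueError("window cannot exceed t_max")


def select_committed(H: Hypergraph, strategy: str, n_committed: int,
                     scores: Mapping[Node, float] | None = None,
                     seed=None) -> set:
    """Choose the committed set under a seeding strategy.

    ``random`` samples uniformly without replacement.  Centrality strategies
    take the ``n_committed`` highest-scoring nodes, resolving ties at the
    boundary uniformly at random within the tied score class.
    """
    if n_committed > H.N:
        raise ValueError("n_committed exceeds the number of nodes")
    rng = np.random.default_rng(seed)
    nodes = list(H.nodes)
    if n_committed == 0:
        return set()
    if strategy == "random":
        idx = rng.choice(H.N, size=n_committed, replace=False)
        return {nodes[i] for i in idx}
    if scores is None:
        raise ValueError(f"strategy {strategy!r} requires scores")
    if set(scores) != set(nodes):
        raise ValueError("scores must cover exactly the hypergraph nodes")
    order = sorted(nodes, key=lambda v: -scores[v])
    cutoff = scores[order[n_committed - 1]]
    chosen = [v for v in order[:n_committed] if scores[v] > cutoff]
    tied = [v for v in nodes if scores[v] == cutoff]
    need = n_committed - len(chosen)
    pick = rng.choice(len(tied), size=need, replace=False)
    chosen.extend(tied[i] for i in pick)
    return set(chosen)


def agreement_possible(states, group, speaker, name, rule: str) -> bool:
    """Whether the uttered name can trigger a group agreement.

    Union rule: at least one *listener* holds the name.  Unanimity rule: all
    group members, speaker included, hold it.  ``states`` maps members to
    dictionary bit codes.
    """
    if rule == "unanimity":
        return all(states[u] & name for u in group)
    if rule == "union":
        return any(states[u] & name for u in group if u != speaker)
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class NGResult:
    """One naming-game trajectory and its stationary summary."""

    n_A_star: float
    absorbed: bool
    t_absorbed: int | None
    committed: frozenset
    trajectory_t: np.ndarray = field(repr=False, default=None)
    trajectory_nA: np.ndarray = field(repr=False, default=None)


def run_ng(H: Hypergraph, params: NGParams, committed: set | None = None,
           scores: Mapping[Node, float] | None = None,
           record_every: int | None = None) -> NGResult:
    """Simulate one naming-game run.

    If ``committed`` is None it is selected per ``params.strategy`` (using
    ``scores`` for the centrality strategies).  ``record_every`` controls the
    sampling stride of the returned trajectory (None: ~1000 points).
    """
    if H.n_edges == 0:
        raise ValueError("naming game needs at least one hyperedge")
    rng = np.random.default_rng(params.seed)
    if committed is None:
        committed = select_committed(H, params.strategy, params.n_committed,
                                     scores=scores, seed=rng)
    N = H.N
    idx = H.node_index()
    edges: list[tuple[int, ...]] = [tuple(sorted(idx[v] for v in e))
                                    for e in H.edge_list]
    is_committed = np.zeros(N, dtype=bool)
    for v in committed:
        is_committed[idx[v]] = True

    state = np.full(N, B, dtype=np.int8)
    state[is_committed] = A
    n_A = int((state == A).sum())

    n_edges = len(edges)
    if record_every is None:
        record_every = max(1, params.t_max // 1000)
    traj_t = [0]
    traj_nA = [n_A / N]
    sample_stride = max(1, params.window // params.n_samples)
    sample_start = params.t_max - params.window
    samples: list[float] = []
    absorbed = n_A == N
    t_absorbed = 0 if absorbed else None

    t = 0
    while not absorbed and t < params.t_max:
        t += 1
        e = edges[rng.integers(n_edges)]
        speaker = e[rng.integers(len(e))]
        sdict = state[speaker]
        if sdict == AB:
            name = A if rng.random() < 0.5 else B
        else:
            name = sdict
        possible = agreement_possible(state, e, speaker, name, params.rule)
        if possible and rng.random() < params.beta:
            for u in e:
                if not is_committed[u]:
                    old = state[u]
                    if old != name:
                        if old == A:
                            n_A -= 1
                        elif name == A:
                            n_A += 1
                        state[u] = name
        else:
            for u in e:
                if u != speaker and not is_committed[u]:
                    old = state[u]
                    new = old | name
                    if new != old:
                        if old == A:
                            n_A -= 1
                        state[u] = new
        if n_A == N:
            absorbed = True
            t_absorbed = t
        if t % record_every == 0 or absorbed:
            traj_t.append(t)
            traj_nA.append(n_A / N)
        if t > sample_start and (t - sample_start) % sample_stride == 0:
            samples.append(n_A / N)

    if absorbed:
        n_A_star = 1.0
    elif samples:
        n_A_star = float(np.mean(samples[-params.n_samples:]))
    else:
        n_A_star = n_A / N
    return NGResult(n_A_star=n_A_star, absorbed=absorbed,
                    t_absorbed=t_absorbed, committed=frozenset(committed),
                    trajectory_t=np.array(traj_t),
                    trajectory_nA=np.array(traj_nA))


def _median_n_A_star(H: Hypergraph, params: NGParams,
                     scores: Mapping[Node, float] | None,
                     ss: np.random.SeedSequence) -> float:
    vals = []
    for child in ss.spawn(params.n_runs):
        p = NGParams(beta=params.beta, n_committed=params.n_committed,
                     rule=params.rule, strategy=params.strategy,
                     t_max=params.t_max, window=params.window,
                     n_samples=params.n_samples, n_runs=params.n_runs,
                     seed=child)
        vals.append(run_ng(H, p, scores=scores).n_A_star)
    return float(median(vals))


def phase_scan(H: Hypergraph, beta_grid: Sequence[float],
               p_grid: Sequence[float], rule: str = "union",
               strategy: str = "random",
               scores: Mapping[Node, float] | None = None,
               t_max: int = 500_000, window: int = 50_000,
               n_samples: int = 100, n_runs: int = 200, seed=None):
    """Median stationary n_A* on a (beta, p) grid.

    Returns a pandas DataFrame with columns beta, p, n_committed and
    median_n_A_star; the takeover region is the set of cells with median 1.
    """
    import pandas as pd

    if len(beta_grid) == 0 or len(p_grid) == 0:
        raise ValueError("empty grid")
    ss = np.random.SeedSequence(seed)
    rows = []
    for beta in beta_grid:
        for p in p_grid:
            n_c = int(round(p * H.N))
            params = NGParams(beta=beta, n_committed=n_c, rule=rule,
                              strategy=strategy, t_max=t_max, window=window,
                              n_samples=n_samples, n_runs=n_runs)
            med = _median_n_A_star(H, params, scores, ss.spawn(1)[0])
            rows.append((beta, p, n_c, med))
    return pd.DataFrame(rows, columns=["beta", "p", "n_committed",
                                       "median_n_A_star"])


def takeover_fraction(scan) -> float:
    """Fraction of grid cells whose median n_A* reaches the absorbing state."""
    return float((scan["median_n_A_star"] >= 1.0).mean())


def critical_mass(H: Hypergraph, beta: float, p_grid: Sequence[float],
                  rule: str = "union", strategy: str = "random",
                  scores: Mapping[Node, float] | None = None,
                  t_max: int = 500_000, window: int = 50_000,
                  n_samples: int = 100, n_runs: int = 200,
                  seed=None) -> float | None:
    """Smallest committed fraction p in the grid achieving median takeover.

    Scans the ascending ``p_grid`` and returns the first p whose median
    n_A* equals 1, or None when no grid point achieves takeover.
    """
    p_grid = list(p_grid)
    if sorted(p_grid) != p_grid:
        raise ValueError("p_grid must be ascending")
    ss = np.random.SeedSequence(seed)
    for p in p_grid:
        n_c = int(round(p * H.N))
        params = NGParams(beta=beta, n_committed=n_c, rule=rule,
                          strategy=strategy, t_max=t_max, window=window,
                          n_samples=n_samples, n_runs=n_runs)
        med = _median_n_A_star(H, params, scores, ss.spawn(1)[0])
        if med >= 1.0:
            return float(p)
    return None
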