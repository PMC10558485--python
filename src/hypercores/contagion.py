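"""Discrete-time higher-order nonlinear SIS/SIR contagion on hypergraphs.

In each time step a susceptible node j becomes infectious with probability

    p_j = 1 - prod_{e in E(j)} exp(-lambda * i_e^nu),

where the product runs over the hyperedges containing j and i_e is the
number of infectious members of e at the start of the step.  nu = 1 recovers
linear contagion; nu > 1 reinforces exposure within large groups.  Every
infectious node independently recovers with probability mu per step, back to
S (SIS) or to R (SIR).  Updates are synchronous on start-of-step states, so
a node infected in a step cannot recover in the same step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .cores import HypercoreProfile
from .hypergraph import Hypergraph, Node


@dataclass
class ContagionParams:
    """Parameters of the nonlinear contagion process.

    lam is the infection scale (per step, in [0, 1]); nu the nonlinearity
    exponent; mu the per-step recovery probability.  For SIS, ``burn_in``
    steps precede an observation window of ``T`` steps; ``t_cap`` is a hard
    per-run step limit (None = burn_in + T for SIS, unlimited for SIR).
    """

    lam: float
    mu: float
    nu: float = 1.0
    model: str = "SIS"
    T: int = 1_000
    burn_in: int = 1_000
    t_cap: int | None = None
    n_runs: int = 300
    seed: object = None

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if not (0 < self.mu <= 1):
            raise ValueError("mu must be in (0, 1]")
        if self.nu <= 0:
            raise ValueError("nu must be > 0")
        if self.model not in ("SIS", "SIR"):
            raise ValueError("model must be 'SIS' or 'SIR'")
        if self.T < 1:
            raise ValueError("T must be >= 1")


def infection_probability(j: Node, infected: Iterable[Node], H: Hypergraph,
                          lam: float, nu: float = 1.0) -> float:
    """Per-step infection probability of susceptible node ``j``.

    Equals ``1 - prod_e exp(-lam * i_e**nu)`` over the hyperedges containing
    j; hyperedges without infectious members contribute a factor 1.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    inf = set(infected)
    if j in inf:
        raise ValueError("node j must be susceptible")
    exponent = 0.0
    for e in H.hyperedges:
        if j in e:
            i_e = len(e & inf)
            if i_e:
                exponent += lam * i_e ** nu
    return -math.expm1(-exponent)


@dataclass
class SISResult:
    """Outcome of repeated SIS runs.

    ``tau`` is the per-run matrix of steps spent infectious within the
    observation window (rows: runs, columns: nodes in ``nodes`` order); runs
    extinct (or capped) before the window completed are flagged in
    ``excluded`` and do not enter the averages.
    """

    nodes: tuple
    tau: np.ndarray
    excluded: np.ndarray
    T: int
    n_extinct: int
    n_capped: int

    @property
    def n_valid(self) -> int:
        return int((~self.excluded).sum())

    def tau_fraction(self) -> dict[Node, float]:
        """Mean tau(j)/T per node over non-excluded runs."""
        ok = ~self.excluded
        if ok.sum() == 0:
            return {v: math.nan for v in self.nodes}
        means = self.tau[ok].mean(axis=0) / self.T
        return {v: float(x) for v, x in zip(self.nodes, means)}


def _incidence(H: Hypergraph) -> sparse.csr_matrix:
    B = H.incidence().astype(np.float64)
    return B


def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def run_sis(H: Hypergraph, params: ContagionParams) -> SISResult:
    """Simulate ``params.n_runs`` SIS runs, each from one uniform random seed.

    After ``burn_in`` steps the number of steps each node spends infectious
    is accumulated over a window of ``T`` steps.  Runs that die out before
    the window completes are recorded (``n_extinct``) and excluded from the
    tau averages, as are runs hitting ``t_cap``.
    """
    if params.model != "SIS":
        raise ValueError("params.model must be 'SIS'")
    B = _incidence(H)
    N = H.N
    t_cap = params.t_cap if params.t_cap is not None else params.burn_in + params.T
    ss = _seed_seq(params.seed)
    tau = np.zeros((params.n_runs, N))
    excluded = np.zeros(params.n_runs, dtype=bool)
    n_extinct = 0
    n_capped = 0
    for r, child in enumerate(ss.spawn(params.n_runs)):
        rng = np.random.default_rng(child)
        x = np.zeros(N, dtype=bool)
        x[rng.integers(N)] = True
        t = 0
        window_done = 0
        while window_done < params.T:
            if not x.any():
                excluded[r] = True
                n_extinct += 1
                break
            if t >= t_cap:
                excluded[r] = True
                n_capped += 1
                break
            i_e = B @ x
            force = B.T @ (i_e ** params.nu)
            p = -np.expm1(-params.lam * force)
            new_inf = (~x) & (rng.random(N) < p)
            recover = x & (rng.random(N) < params.mu)
            x = (x & ~recover) | new_inf
            t += 1
            if t > params.burn_in:
                tau[r] += x
                window_done += 1
    return SISResult(nodes=H.nodes, tau=tau, excluded=excluded, T=params.T,
                     n_extinct=n_extinct, n_capped=n_capped)


@dataclass
class SIRSeedResult:
    """Final epidemic sizes of SIR runs from a fixed seed node."""

    seed_node: Node
    sizes: np.ndarray

    @property
    def mean_final_size(self) -> float:
        return float(self.sizes.mean())

    @property
    def stderr(self) -> float:
        if len(self.sizes) < 2:
            return math.nan
        return float(self.sizes.std(ddof=1) / math.sqrt(len(self.sizes)))


def run_sir_seed(H: Hypergraph, params: ContagionParams,
                 seed_node: Node) -> SIRSeedResult:
    """Average final size R_inf of SIR outbreaks seeded at ``seed_node``.

    Each of ``params.n_runs`` independent runs starts with only the seed
    infectious and iterates until no infectious node remains.
    """
    if params.model != "SIR":
        raise ValueError("params.model must be 'SIR'")
    if seed_node not in H.node_index():
        raise ValueError(f"unknown seed node {seed_node!r}")
    B = _incidence(H)
    N = H.N
    j0 = H.index_of(seed_node)
    ss = _seed_seq(params.seed)
    sizes = np.zeros(params.n_runs)
    for r, child in enumerate(ss.spawn(params.n_runs)):
        rng = np.random.default_rng(child)
        x = np.zeros(N, dtype=bool)   # infectious
        rec = np.zeros(N, dtype=bool)  # recovered
        x[j0] = True
        t = 0
        while x.any():
            if params.t_cap is not None and t >= params.t_cap:
                break
            i_e = B @ x
            force = B.T @ (i_e ** params.nu)
            p = -np.expm1(-params.lam * force)
            new_inf = (~x) & (~rec) & (rng.random(N) < p)
            recover = x & (rng.random(N) < params.mu)
            rec |= recover
            x = (x & ~recover) | new_inf
            t += 1
        sizes[r] = rec.sum() + x.sum()
    return SIRSeedResult(seed_node=seed_node, sizes=sizes)


def run_sir_all_seeds(H: Hypergraph, params: ContagionParams) -> dict[Node, float]:
    """Per-node spreading power: mean R_inf when seeding at each node."""
    ss = _seed_seq(params.seed)
    out: dict[Node, float] = {}
    for v, child in zip(H.nodes, ss.spawn(H.N)):
        p = replace(params, seed=child)
        out[v] = run_sir_seed(H, p, v).mean_final_size
    return out


def aggregate_by_core(values: Mapping[Node, float],
                      profile: HypercoreProfile) -> pd.DataFrame:
    """Average a per-node quantity over the nodes of each (k, m)-hyper-core.

    Returns a tidy frame (m, k, core_size, mean); empty cores are omitted.
    Raises if the node universes disagree.
    """
    if set(values) != set(profile.nodes):
        raise ValueError("node set of values does not match the profile")
    rows = []
    for m in sorted(profile.shell_index):
        for k in range(1, profile.kmax.get(m, 0) + 1):
            core = profile.core(k, m)
            if not core:
                continue
            mean = float(np.mean([values[v] for v in core]))
            rows.append((m, k, len(core), mean))
    return pd.DataFrame(rows, columns=["m", "k", "core_size", "mean"])
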