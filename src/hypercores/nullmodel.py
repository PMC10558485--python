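"""Degree-preserving hypergraph randomization and z-score profiles.

The shuffling chain repeatedly picks two distinct hyperedges of the same size
m, one random node in each, and exchanges them.  A proposed swap is rejected
when either resulting hyperedge would duplicate an existing hyperedge or
contain a repeated node.  Accepted swaps preserve, exactly: the node count N,
the number of hyperedges of every size, and the full degree vector d(i) of
every node.  Sizes with fewer than 4 hyperedges are left untouched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cores import decompose
from .hypergraph import Hypergraph

logger = logging.getLogger(__name__)

#: default number of accepted swaps per hyperedge size
DEFAULT_SWAPS_PER_SIZE = 100_000
#: default number of shuffled realizations in a z-score profile
DEFAULT_REALIZATIONS = 1_000
#: attempts allowed per accepted swap before giving up on a size
REJECTION_FACTOR = 100


def shuffle(H: Hypergraph, swaps_per_size: int = DEFAULT_SWAPS_PER_SIZE,
            seed=None) -> Hypergraph:
    """Return an independently shuffled copy of ``H``.

    For each hyperedge size with at least 4 hyperedges, ``swaps_per_size``
    accepted swaps are performed; a rejection cap of ``REJECTION_FACTOR``
    times the target guarantees termination on rigid instances (a warning is
    logged when the cap is hit).
    """
    if swaps_per_size < 0:
        raise ValueError("swaps_per_size must be >= 0")
    rng = np.random.default_rng(seed)
    by_size: dict[int, list[frozenset]] = {}
    for e in H.edge_list:
        by_size.setdefault(len(e), []).append(e)
    present: set[frozenset] = set(H.hyperedges)

    for m in sorted(by_size):
        edges = by_size[m]
        if len(edges) < 4:
            logger.info("size %d has %d < 4 hyperedges; not shuffled",
                        m, len(edges))
            continue
        accepted = 0
        attempts = 0
        cap = REJECTION_FACTOR * swaps_per_size
        n_m = len(edges)
        while accepted < swaps_per_size and attempts < cap:
            attempts += 1
            a = int(rng.integers(n_m))
            b = int(rng.integers(n_m - 1))
            if b >= a:
                b += 1
            e, f = edges[a], edges[b]
            i = sorted(e, key=repr)[int(rng.integers(m))]
            j = sorted(f, key=repr)[int(rng.integers(m))]
            if j in e or i in f:        # repeated node (includes i == j)
                continue
            e2 = (e - {i}) | {j}
            f2 = (f - {j}) | {i}
            if e2 in present or f2 in present:
                continue
            present.discard(e)
            present.discard(f)
            present.add(e2)
            present.add(f2)
            edges[a], edges[b] = e2, f2
            accepted += 1
        if accepted < swaps_per_size:
            logger.warning("size %d: only %d/%d swaps accepted before the "
                           "rejection cap", m, accepted, swaps_per_size)
    return Hypergraph(present, nodes=H.nodes)


@dataclass
class NullEnsembleSummary:
    """Per-(k, m) comparison of empirical hyper-core sizes with a null ensemble.

    ``table`` has one row per (m, k) cell with columns ``n_emp``,
    ``null_mean``, ``null_std`` (sample estimator), ``z`` and ``defined``;
    cells with zero null variance carry ``defined = False`` and NaN z (treated
    as non-significant).  ``significant`` marks defined cells with |z| >= 1.96.
    """

    table: pd.DataFrame
    n_realizations: int
    swaps_per_size: int
    seed: object

    @property
    def significant_fraction(self) -> float:
        """Fraction of *defined* cells with |z| >= 1.96."""
        defined = self.table[self.table["defined"]]
        if len(defined) == 0:
            return float("nan")
        return float((defined["z"].abs() >= 1.96).mean())

    def z(self, k: int, m: int) -> float:
        row = self.table[(self.table["m"] == m) & (self.table["k"] == k)]
        if row.empty:
            raise KeyError(f"no ({k}, {m}) cell in the summary")
        return float(row["z"].iloc[0])


def z_profile(H: Hypergraph, n_realizations: int = DEFAULT_REALIZATIONS,
              swaps_per_size: int = DEFAULT_SWAPS_PER_SIZE,
              seed=None) -> NullEnsembleSummary:
    """z-scores of the relative hyper-core sizes n_(k,m) against shuffles.

    Decomposes ``H`` and ``n_realizations`` independent shuffles; a (k, m)
    cell absent from a realization counts as relative size 0.
    """
    if n_realizations < 2:
        raise ValueError("need at least 2 realizations for a standard deviation")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_realizations)

    def profile_cells(G: Hypergraph) -> dict[tuple[int, int], float]:
        prof = decompose(G)
        cells = {}
        for m in sorted(prof.shell_index):
            for k in range(1, prof.kmax.get(m, 0) + 1):
                cells[(m, k)] = prof.n(k, m)
        return cells

    emp = profile_cells(H)
    null_cells: list[dict] = []
    for child in child_seeds:
        Hs = shuffle(H, swaps_per_size=swaps_per_size, seed=child)
        null_cells.append(profile_cells(Hs))

    all_keys = set(emp)
    for cells in null_cells:
        all_keys.update(cells)

    rows = []
    for (m, k) in sorted(all_keys):
        vals = np.array([cells.get((m, k), 0.0) for cells in null_cells])
        mean = float(vals.mean())
        std = float(vals.std(ddof=1))
        n_emp = emp.get((m, k), 0.0)
        defined = std > 0.0
        z = (n_emp - mean) / std if defined else math.nan
        rows.append((m, k, n_emp, mean, std, z, defined,
                     defined and abs(z) >= 1.96))
    table = pd.DataFrame(rows, columns=["m", "k", "n_emp", "null_mean",
                                        "null_std", "z", "defined",
                                        "significant"])
    return NullEnsembleSummary(table=table, n_realizations=n_realizations,
                               swaps_per_size=swaps_per_size, seed=seed)
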