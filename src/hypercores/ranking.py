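"""Ranking-comparison utilities: top-fN overlaps, top-f averages, correlations.

These serve to compare centrality rankings (hypercoreness, s-coreness,
k-coreness) with dynamical importance rankings (tau/T in SIS steady states,
mean SIR final sizes).  Top sets have ceil(f*N) members; score ties at the
selection boundary are resolved uniformly at random under a seed, so averaged
results over replicates are well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

Node = object


def top_f_nodes(scores: Mapping, f: float, seed=None) -> set:
    """The ceil(f*N) top-scoring nodes, boundary ties broken at random."""
    if not (0 < f <= 1):
        raise ValueError("f must be in (0, 1]")
    if not scores:
        raise ValueError("empty score map")
    n_top = math.ceil(f * len(scores))
    rng = np.random.default_rng(seed)
    nodes = sorted(scores, key=repr)
    order = sorted(nodes, key=lambda v: -scores[v])
    cutoff = scores[order[n_top - 1]]
    chosen = {v for v in order[:n_top] if scores[v] > cutoff}
    tied = [v for v in nodes if scores[v] == cutoff]
    need = n_top - len(chosen)
    pick = rng.choice(len(tied), size=need, replace=False)
    chosen.update(tied[i] for i in pick)
    return chosen


def jaccard_top_f(score_a: Mapping, score_b: Mapping, f: float,
                  seed=None) -> float:
    """Jaccard coefficient |A ∩ B| / |A ∪ B| between the two top-fN sets."""
    if set(score_a) != set(score_b):
        raise ValueError("score maps must cover the same node set")
    ss = np.random.SeedSequence(seed)
    sa, sb = ss.spawn(2)
    top_a = top_f_nodes(score_a, f, seed=sa)
    top_b = top_f_nodes(score_b, f, seed=sb)
    return len(top_a & top_b) / len(top_a | top_b)


def top_f_average(scores: Mapping, metric: Mapping, f: float,
                  seed=None) -> float:
    """Mean of ``metric`` over the top-fN nodes of ``scores``."""
    if set(scores) != set(metric):
        raise ValueError("score and metric maps must cover the same node set")
    top = top_f_nodes(scores, f, seed=seed)
    if not top:
        raise ValueError("empty top selection")
    return float(np.mean([metric[v] for v in top]))


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson rho and tie-adjusted Kendall coefficient (NaN = undefined)."""

    pearson: float
    kendall: float

    @property
    def pearson_defined(self) -> bool:
        return not math.isnan(self.pearson)

    @property
    def kendall_defined(self) -> bool:
        return not math.isnan(self.kendall)


def correlations(score_a: Mapping, score_b: Mapping) -> CorrelationResult:
    """Pearson and Kendall (tau-b) coefficients over the common node set.

    A constant vector leaves the affected coefficient undefined (NaN).
    """
    common = sorted(set(score_a) & set(score_b), key=repr)
    if len(common) < 3:
        raise ValueError("need at least 3 common nodes")
    a = np.array([score_a[v] for v in common], dtype=float)
    b = np.array([score_b[v] for v in common], dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        pearson = math.nan
    else:
        pearson = float(stats.pearsonr(a, b).statistic)
    kendall = float(stats.kendalltau(a, b).statistic)
    return CorrelationResult(pearson=pearson, kendall=kendall)
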