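# Methods

## Hypergraph model

A hypergraph is stored as a set of nodes plus a *set* of hyperedges
(frozensets of node labels). Set semantics are intrinsic: duplicate input
hyperedges are merged (a count is kept and logged by the readers) and
singleton hyperedges are dropped, since every quantity in the package starts
at group size m = 2. Labels are opaque hashables; a stable label-to-dense-
index map is maintained internally and all computational kernels work on
integer indices, so results never depend on label types or ordering.

Preprocessing covers the three common data shapes. Timestamped pairwise
contacts are aggregated over fixed, non-overlapping half-open windows
`[t0 + w·q, t0 + w·(q+1))` anchored at the first event, with w = 900 s by
default, the standard aggregation scale for proximity-sensor data; within a
window, each maximal clique (networkx's pivoting Bron–Kerbosch) of the
contact graph becomes a hyperedge. Whether such windows should overlap or be
anchored differently is a genuinely open choice; fixed non-overlapping
windows anchored at the first event are the simplest reproducible rule and
the one implemented. Bipartite records (e.g. plant–pollinator) are projected
by turning each node of one side into the hyperedge of its neighbours on the
other side. Direction in communication data is intentionally discarded: a
hyperedge is an unordered group.

The weighted pairwise projection expands every hyperedge into a clique,
weighting edge (i, j) by the number of distinct hyperedges containing both.
Its s-coreness uses successive minimum-strength peeling (valid because
weights are positive integers): S(i) is the largest integer s such that i
survives in the maximal subgraph with all strengths ≥ s. The k-coreness is
networkx's core number on the unweighted projection.

## Hyper-core decomposition

The (k, m)-hyper-core peeling removes every node with fewer than k current
hyperedges of size ≥ m; removing a node shrinks the hyperedges containing
it, and a shrunk hyperedge is deleted when it drops below size m *or* when
it coincides with any hyperedge currently present — including a collision
between two shrunk hyperedges. This uniform dedup rule makes the peeling
agree exactly with the defining property of the induced subhypergraph
(hyperedges are intersections with the surviving node set, deduplicated),
which is what the exhaustive test oracle checks: the defining property is
closed under union of node sets, so the maximum subhypergraph is the union
of all valid subsets and can be found by brute force on small instances.

The full profile iterates k upward within each m, reusing the surviving
(possibly shrunk) subhypergraph from level k as the starting point for
k + 1; nesting in k guarantees correctness, and the test suite re-verifies
every cell against independent per-cell peeling. Removal order within a
peeling round is ascending internal index purely for log determinism — the
result is order-invariant (tested under random relabelings). Only core
*node sets* are exported; induced hyperedge sets are an implementation
detail of the peeling state.

Hypercoreness handles the degenerate size level k_max^m = 0 (possible only
on restricted profiles) by letting that m contribute 0 rather than 0/0,
which keeps R_g finite and is consistent with C_m = 0 for excluded nodes.
Nodes absent from every hyperedge of size ≥ m keep C_m = 0 and still appear
in score tables, so output schemas are stable across hypergraphs.

## Null model

The randomization chain repeatedly selects two distinct hyperedges of equal
size and exchanges one uniformly chosen node between them, rejecting the
swap if a resulting hyperedge would duplicate an existing one or contain a
repeated node (the incoming node already belongs to the target — sets cannot
hold a node twice, and the no-op i = j case falls out of the same rule).
Accepted swaps exactly preserve the hyperedge-size histogram and every
node's full degree vector d(i). Sizes with fewer than 4 hyperedges are left
untouched: with 2–3 hyperedges of a size the chain cannot move without
creating duplicates.

The loop counts *accepted* swaps, with a rejection cap of 100× the target to
guarantee termination on rigid instances (a warning is logged when hit).
Defaults are 10^5 swaps per size and 10^3 realizations — appropriate for
empirical data sets — while tests and the acceptance script scale both down
to desk scale (order 10^2) since the fixtures have tens of hyperedges.

z-scores standardize the empirical relative core size n_(k,m) against the
shuffled ensemble; a cell absent from a realization counts as 0, the
standard deviation is the sample estimator (ddof = 1), and cells with zero
null variance are flagged undefined and rendered non-significant rather
than given an infinite score. The |z| < 1.96 band marks the two-sided 5%
level. Note that for deep cells the null distribution is strongly
non-Gaussian (often a point mass at 0 plus rare large cores), so z is a
descriptive effect-size summary, not an exact test statistic.

## Nonlinear contagion

Susceptible node j is infected in a step with probability
`1 − Π_{e∋j} exp(−λ i_e^ν)` (i_e = infectious members of e at the start of
the step), and every infectious node recovers with probability μ. Updates
are synchronous on start-of-step states and a node infected in a step
cannot recover in that same step. Discrete time with unspecified ordering
admits several conventions; this one was chosen because it makes the
two-node systems exactly solvable, which the tests exploit: the SIR pair
has mean final size `1 + q/(1 − (1−q)(1−μ))` with `q = 1 − e^{−λ}`, and the
SIS pair reduces to a four-state Markov chain whose window occupancy,
conditioned on non-extinction, is computed by transition-matrix powering.

SIS runs start from one uniformly random infectious seed, discard a
configurable burn-in (default 10^3 steps, matching the observation window
T = 10^3), then accumulate each node's infectious time τ(j) over T steps.
There is no reliable online test for "the steady state has been reached",
so the fixed burn-in is the documented stand-in; runs that go extinct (or
hit the step cap) before the window completes are counted and excluded from
localization averages, which is appropriate in the intended parameter
regimes where extinction is rare. SIR runs iterate until no infectious node
remains and report the mean final size over replicates (default 300 per
seed). Per-run randomness derives from a master seed through spawned
`numpy` SeedSequences, so every result is replayable bit for bit.

## Naming game

Dictionaries are non-empty subsets of {A, B}, encoded as 2-bit integers.
Per step: a hyperedge is chosen uniformly from the deduplicated hyperedge
set (no size weighting), a speaker uniformly within it, and a name
uniformly from the speaker's dictionary. The union rule asks whether at
least one *listener* holds the name; the unanimity rule asks whether *all
group members including the speaker* hold it — the asymmetry is
deliberate and preserved. A possible agreement becomes effective with
probability β, collapsing every non-committed member's dictionary (speaker
included) to the uttered name; otherwise every non-committed listener adds
the name. Committed nodes hold {A} forever, may act as speakers (always
uttering A), and are never updated; a non-committed speaker is left
unchanged on failure since it already holds what it uttered.

n_A counts nodes whose dictionary is exactly {A}, committed included. A run
absorbs at n_A = 1 (verified absorbing: no rule can then introduce B) or
stops at t_max (default 5×10^5); the stationary n_A* is then the mean of
100 samples spaced evenly over the last 5×10^4 steps. Phase scans report
per-cell medians over replicate runs, and the critical mass p_c is the
smallest grid fraction whose median reaches 1 (a None sentinel when absent).
Committed sets are re-selected per run; centrality-based strategies break
boundary ties uniformly at random within the tied score class.

## Ranking comparisons

Top sets contain ⌈fN⌉ nodes; the tie policy at the selection boundary is
uniform random under a seed (no policy is canonical; the random one is
unbiased and, averaged over replicates, gives well-defined mean overlaps).
Pearson and tie-adjusted Kendall (tau-b) coefficients come from
scipy.stats; constant vectors leave the affected coefficient undefined
(NaN) rather than raising.

## Synthetic fixtures

The random generator draws the requested number of *distinct* uniform
m-subsets per size by rejection, validating counts against C(N, m). The
planted-core generator covers n_core nodes with distinct size-m_core
hyperedges until every planted node lies in at least k_core of them
(greedily extending the least-covered node), which guarantees the planted
set is contained in the (k_core, m_core)-hyper-core; every periphery node
attaches by a single pairwise edge, so peripheral shell indices vanish for
m ≥ 3. Optional extra random hyperedges over the whole node set control how
much room the null-model shuffler has to dilute the planted structure.

`toy_hypergraph()` is a hand-built 14-node hypergraph whose full decomposition
is frozen in the test suite from the exhaustive oracle. It was designed to
exercise the decomposition's subtleties: a node with D_3 = 2 that the
(2, 3) peeling nevertheless removes (its groups shrink and collide), a
pairwise triangle that enters the (2, 2)-core only, and a strict nesting
chain (2,3) ⊂ (2,2) ⊂ (1,2).

## What the synthetic fixtures do and do not show

The generators emulate the features the methods rely on — heterogeneous
hyperedge sizes, a dense planted core against a sparse periphery, degree
heterogeneity — at tens of nodes. They do not reproduce heavy-tailed
degree/size distributions, community structure or the scale (10^3–10^5
nodes) of empirical collections, so passing tests certify the correctness
and the *direction* of the effects (localization in deep cores, lower
critical mass under hypercoreness seeding), not empirical effect sizes.
Problem sizes in the tests and the acceptance script (fixtures of 26–50
nodes, 10^2 realizations, 10^2–10^4 stochastic runs, t_max of a few
thousand steps) were chosen as the smallest scales at which those
directional effects are statistically unambiguous.

## Known limitations

- The shuffling chain is the standard swap chain, not an exact uniform
  sampler of the degree-constrained ensemble; on rigid instances it may
  terminate at the rejection cap with fewer accepted swaps.
- Hyperedge-level coreness, streaming/approximate core maintenance, and
  directed or temporal hypergraph semantics are out of scope.
- The naming game is the minimal two-name variant; dictionaries are capped
  at {A, B}.
- The peeling is the straightforward O(M(N + |E| log |E|))-style
  implementation; the optimized bipartite-core algorithms from the
  two-mode-core literature are not implemented.
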