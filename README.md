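# hypercores

Tools for analysing group interactions — hypergraphs — beyond pairwise
networks: the **(k, m)-hyper-core decomposition**, the derived
**hypercoreness** centralities, a degree-preserving **null model**, and two
families of higher-order dynamics (**nonlinear SIS/SIR contagion** and a
**naming game with committed minorities**) used to probe which nodes drive
spreading and consensus processes.

It is aimed at researchers in network epidemiology, computational social
science and ecology who work with group-interaction data: face-to-face
proximity contacts, email threads, committee memberships, plant–pollinator
records, and similar.

## The decomposition

A hypergraph `H = (V, E)` has `N` nodes and hyperedges `e ⊆ V` with
`|e| = m ≥ 2`; `D_m(i)` counts the hyperedges of size at least `m` that
contain node `i`. The **(k, m)-hyper-core** is the maximum subhypergraph,
with hyperedges of size at least `m`, in which every node satisfies
`D_m(i) ≥ k` *within the subhypergraph*. It is computed by recursive
removal: delete every node with fewer than `k` qualifying hyperedges; each
removal shrinks the hyperedges containing that node, and a shrunk hyperedge
is dropped when it falls below size `m` or collides with one already
present. Cores nest in both `k` and `m`.

The **m-shell index** `C_m(i)` is the deepest `k` at which node `i`
survives, and `k_max^m` the deepest non-empty core at size `m`. The
**hypercoreness** aggregates shell depths across sizes:

    R_g(i) = Σ_{m=2}^{M} g(m) · C_m(i) / k_max^m

with `g ≡ 1` giving the size-independent hypercoreness `R ∈ [0, M−1]` and
`g = Ψ` (the empirical hyperedge-size frequency) the frequency-based
`R_w ∈ [0, 1]`. These rank nodes by how deeply they sit in the double
hierarchy, and the package compares them against the `s`-coreness and
`k`-coreness of the weighted pairwise projection.

## Worked example

```python
import hypercores as hc

H = hc.toy_hypergraph()            # 14 nodes, 7 group + 6 pairwise interactions
prof = hc.decompose(H)
print(prof.kmax)               # {2: 3, 3: 3}
print(sorted(prof.core(2, 3))) # [1, 2, 3, 4]
print(H.degree_at_least(8, 3), prof.shell_index[3][8])  # 2 1

R = hc.size_independent_hypercoreness(prof)
print(round(R[1], 3), round(R[8], 3))  # 2.0 0.667
```

Node 8 sits in two size-3 hyperedges (`D_3 = 2`) yet has shell index
`C_3 = 1`: its groups collapse during the `(2, 3)` peeling — membership
counts alone do not make a node central. Node 1, inside the dense
3-uniform cluster, reaches the deepest shell at every size and the maximal
hypercoreness `R = 2`.

Dynamics hang off the same objects:

```python
spec = hc.FixtureSpec(n_nodes=26, seed=42,
                      planted=hc.PlantedCoreSpec(n_core=12, k_core=3, m_core=3))
H, core = hc.planted_core_hypergraph(spec)
params = hc.ContagionParams(lam=0.05, nu=1.5, mu=0.1, model="SIS",
                            T=500, burn_in=300, n_runs=100, seed=0)
frac = hc.run_sis(H, params).tau_fraction()   # per-node tau/T
```

On this fixture the planted-core nodes spend roughly 0.72 of the
observation window infectious against roughly 0.25 for the periphery — the
steady state localizes in the deep hyper-core.

A command-line interface mirrors the library:
`hypercores convert|decompose|centrality|nullmodel|sis|sir|ng|ng-scan|compare|synth`
(see `hypercores --help`).

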