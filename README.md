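# coocnet

Co-occurrence network analysis of microbial relative-abundance tables, built
for the comparison of two cohorts — e.g. a healthy control population against
a disease population — at every scale of network organization.

Gut microbiome studies yield species × sample relative-abundance matrices.
Species that tend to be present *together* across subjects form a
co-occurrence network, and changes in that network's topology (rather than in
single-species abundances) can characterize disease states: dissolved
species communities, new inter-module hub species, weakened rich-club
organization, and altered robustness to species removal.

## The model

From an abundance table with species profiles x, y over samples, pairwise
similarity is the abundance-weighted (Ružička) Jaccard index

```
J(x, y) = Σ_s min(x_s, y_s) / Σ_s max(x_s, y_s)   ∈ [0, 1]
```

An undirected binary network keeps the edge (i, j) iff J_ij exceeds the
off-diagonal mean by more than one standard deviation (a data-adaptive cut
retaining roughly the strongest fifth of co-occurrences). On that network the
package computes:

* **global metrics** — average clustering coefficient C, characteristic path
  length PL, global efficiency E, diameter, against degree-preserving
  rewired and ring-lattice benchmarks;
* **motif census** — all connected induced 3- and 4-node subgraphs, with
  degree-adjusted (OLS-residual) per-species participation;
* **eigenvector centrality** — x_i = (1/λ) Σ_j A_ij x_j by power iteration,
  and cross-network differentials;
* **consensus communities** — modularity
  Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(C_i, C_j) maximized by a seeded
  Louvain algorithm, repeated many times and distilled into a consensus
  partition via the co-assignment agreement matrix; partitions compared with
  the Rand index plus a label-permutation null;
* **node roles** — intra-module degree Z-score and participation coefficient
  P = 1 − Σ_s (a_is/a_i)², tiled into six roles (provincial / peripheral /
  connector × hub / non-hub);
* **rich club** — ϕ(k) = E_>k / (n_k(n_k−1)/2), normalized by a rewired
  ensemble, with per-k permutation significance and a functional permutation
  comparison of two cohorts' curves;
* **percolation** — random and targeted (highest-degree-first) node removal,
  tracking E, diameter and largest-component size, with replicate-based
  permutation comparison of attack curves.

A synthetic-data module generates two-cohort tables with planted modular
structure — a conserved core, dissolvable peripheral modules, promotable
cross-module hubs — so every stage can be validated against ground truth
without any external data.

## Worked example

```python
from coocnet import cooccurrence, communities, graph_core, synthetic_data

healthy_spec, disease_spec = synthetic_data.metahit_like_specs(seed=0)
for name, spec in (("healthy", healthy_spec), ("disease", disease_spec)):
    table, truth = synthetic_data.generate_cohort(spec)
    net, removed = cooccurrence.build_network(table)
    gm = graph_core.global_metrics(net)
    res = communities.consensus(net, n_runs=100, seed=1)
    print(f"{name}: {gm.n_nodes} nodes, {gm.n_edges} edges "
          f"({len(removed)} isolates pruned)")
    print(f"  C = {gm.C:.3f}   PL = {gm.PL:.2f}   E = {gm.E:.3f}")
    print(f"  Q = {res.Q_mean:.3f} +/- {res.Q_sd:.3f} over 100 optimizations; "
          f"consensus finds {res.consensus_partition.n_communities} communities")
```

prints

```
healthy: 127 nodes, 1729 edges (23 isolates pruned)
  C = 0.849   PL = 2.27   E = 0.486
  Q = 0.703 +/- 0.000 over 100 optimizations; consensus finds 7 communities
disease: 125 nodes, 1421 edges (25 isolates pruned)
  C = 0.636   PL = 2.36   E = 0.513
  Q = 0.305 +/- 0.009 over 100 optimizations; consensus finds 7 communities
```

The disease cohort — whose generative model dissolves two of the planted
modules and promotes four species to cross-module hubs — shows the expected
signature: lower clustering and a much lower modularity than the control
cohort, while both remain far above what a degree-matched random network
would produce. The same comparison is available end-to-end from the shell:

```
coocnet simulate --out-dir sim --seed 0
coocnet build sim/healthy.tsv --out-dir net_h
coocnet build sim/disease.tsv --out-dir net_d
coocnet compare net_h/edges.tsv net_d/edges.tsv --out-dir report --seed 0
```

which writes a self-contained report directory (JSON summary plus TSV tables
for centrality differentials, role shifts, rich-club curves and percolation
traces, with every stage's seed recorded).

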