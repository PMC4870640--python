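# Methods

This note records the package's modelling choices, numerical conventions and
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Similarity and thresholding

Similarity between two species' abundance profiles is the abundance-weighted
(Ružička) Jaccard index J = Σ min / Σ max over samples. It is computed via
the identity Σ min(x,y) = (‖x‖₁ + ‖y‖₁ − ‖x−y‖₁)/2, valid for non-negative
profiles, so the full matrix is one Manhattan `pdist` call. Two all-zero
profiles score 0 by convention; the diagonal is defined as 1; results are
clipped to [0, 1] to absorb float round-off. The distance 1 − J is a true
metric (Steinhaus form), which the null-model module exploits as an exact
invariant.

The binary network keeps edge (i, j) iff J_ij **strictly** exceeds
mean + m·sd of the off-diagonal upper-triangle values, population sd,
**zeros included** — zero similarities are genuine observations of
non-co-occurrence and must dilute the mean for the one-sd rule to select
only the strong tail. The multiplier m defaults to 1 and a sensitivity sweep
over {0.5, 1.0, 1.5} is built in (`cooccurrence.threshold_sweep`). Ties at
the cutoff are excluded. Isolated species are pruned as an explicit, logged
step, and two cohort networks are harmonized onto the union of species with
at least one connection in at least one network.

## Global metrics

Clustering uses the standard local coefficient with degree-<2 nodes
contributing 0 and included in the average — the only convention under which
the triangle-plus-pendant motif scores 7/12 ≈ 0.583. Path metrics come from
unweighted BFS all-pairs distances (scipy csgraph): PL averages finite
distances over connected pairs only (NaN when none exist); E averages 1/d
over all ordered pairs with 1/∞ = 0; the diameter is the largest finite
distance, i.e. the diameter of the largest component. These conventions keep
every quantity defined on the fragmenting graphs produced by percolation.

## Null models

The random benchmark is degree-preserving Maslov–Sneppen rewiring:
10·|E| *attempted* double-edge swaps (a standard mixing heuristic),
rejecting self-loops and multi-edges; degree sequences are conserved
exactly, and a graph admitting no legal swap (e.g. complete) is returned
unchanged with a warning flag. The lattice benchmark is a deterministic ring
lattice: nearest-neighbour rings filled in offset order, the outermost
partial ring placed by node index, hitting the edge budget exactly. Note
that for small n an outer offset can wrap (n=6 with offsets {1,2} is the
octahedron), so clustering values there differ from the generic large-n ring
formula.

For the triangle-inequality audit of binary nulls, the source network's
retained similarities are randomly permuted onto the rewired edges and
non-edges get similarity 0; the audit counts triplets whose longest side
exceeds the sum of the other two, with a 1e-12 absolute tolerance so that
exact-metric inputs are never flagged by rounding. How edge weights should
be assigned to a binary null is genuinely underdetermined; the permutation
scheme is this package's documented choice.

## Motifs

Motifs are **induced** connected subgraphs (each node subset counted once),
enumerated with the ESU algorithm. The 4-node classes are canonically
ordered by (edge count, sorted degree sequence): star, path, tadpole, cycle,
diamond, clique; at 4 nodes that key is a complete isomorphism invariant.
Profile comparison is a chi-squared homogeneity test on the two count
vectors, with a Monte Carlo fallback (fixed-margin random tables) flagged
whenever an expected cell drops below 5, and a leave-one-out pass that
attributes a significant difference to the classes whose removal destroys
it. Per-species participation is degree-adjusted by OLS of count on degree;
residuals are z-scored within each network ("normalized participation") so
cross-network differentials compare like with like.

## Centrality

Eigenvector centrality is computed by power iteration on the largest
connected component (the Perron vector is component-local; other components
score 0 and are flagged). Iteration uses A + I — same eigenvectors, but the
dominant eigenvalue becomes strictly largest in modulus so bipartite-like
graphs also converge; the reported λ subtracts the shift. Convergence is
max-norm change < tol (default 1e-10); scores are max-normalized so that
differentials are comparable across networks of different size.

## Communities

Modularity uses strengths (= degrees on binary graphs) with resolution γ
(default 1.0, exposed in config). The optimizer is a seeded Louvain: random
sweep order, best-gain local moves (ties to the first candidate in the
randomized order), aggregation with self-loops carrying twice the internal
weight, repeated until no move improves. A single greedy run cannot
guarantee the global optimum — from the all-singleton start a chain of
individually improving moves can occasionally terminate in the all-in-one
state — so `louvain` exposes `n_restarts` (best-of-k over derived seeds,
default 1) and every pipeline use embeds the optimizer in repeated runs.

The consensus procedure runs the optimizer n times (default 1000), collects
the node-pair co-assignment frequency matrix, zeroes entries at or below the
co-assignment level expected from randomly permuted partitions (computed
from each run's block sizes), re-clusters the thresholded weighted agreement
graph with the same optimizer, and iterates until all runs return the same
partition (cap 50 iterations, then a convergence error). Direct
majority-voting is ill-defined under label permutation; agreement-matrix
reclustering honors "most likely community" through co-assignment
frequency. Reported alongside: Q mean ± sd over the initial runs and the
distribution of community counts.

Partition similarity uses the plain (unadjusted) Rand index — under a
label-permutation null it centers near its analytic expectation rather than
0, which is the behaviour the permutation test asserts. One-sided p-values
carry a +1 pseudo-count.

## Node roles

Z_i standardizes a node's intra-module degree against its module's
distribution using the **population** sd (the standard Guimerà-style
formulation); modules of size 1 or zero spread give Z = 0, flagged. P is
1 − Σ (a_is/a_i)², 0 for isolated nodes. Six role tiles: Z > 0 vs Z ≤ 0
crossed with P < 0.2 / [0.2, 0.55) / ≥ 0.55; boundary values go to the
higher-P tile. Absolute inter-module edge counts are reported next to P so
that low-degree nodes cannot masquerade as connectors.

## Rich club

ϕ(k) removes all nodes with *original* degree ≤ k and takes the edge
density of the remainder, masked when fewer than two nodes survive; k runs
from 0 to max degree − 1. Normalization divides by the mean curve of a
degree-preserving ensemble (default 1000 members), with a per-k one-sided
pseudo-counted p (fraction of null curves at or above the observed one).
For curve comparison, the "individual observations" entering the functional
permutation test are the per-replicate normalized curves ϕ(k)/ϕ_r(k) — the
only replicated objects in the procedure; group labels are shuffled and the
difference of group means recomputed per k.

## Percolation

Attacks remove nodes one at a time to complete destruction: uniformly at
random, or the currently highest-degree node with degrees recomputed after
each removal (adaptive targeting; a flag switches to fixed initial-degree
order) and ties broken uniformly at random. Metrics per step follow the
graph-core conventions, so diameter is that of the largest remaining
component. Replicate traces are interpolated onto a common removed-fraction
grid (101 points) and compared by whole-trace label permutation, with an
earliest-significant-fraction summary.

## Synthetic cohorts

The generator emulates a deep-sequencing abundance study at the scale of
roughly 150 bacterial species over ~100 control and ~25 disease subjects:
species are partitioned into latent modules (one conserved core, one
structureless background); each sample activates each module independently
(default probability 0.5); members of active modules are present with high
probability (default 0.9–0.95), everything else at a low baseline (default
0.02–0.05); present species draw independent log-normal abundances (default
location 0, scale 1 — the simplest heavy-tailed positive law; real studies
provide abundances, not a generative model, so every distributional choice
here is an artifact choice); columns are normalized, entries below a
detection floor zeroed (emulating detection sensitivity on relative
abundance — genome coverage has no desk-scale analogue) and renormalized.
One integer seed drives everything through per-sample derived substreams,
so tables are bit-reproducible.

The disease perturbation dissolves chosen modules (members revert to
baseline presence; the core module is guarded) and promotes chosen species
to cross-module hubs whose presence tracks overall module activity — making
them co-occur with each other and with every module, the planted analogue
of newly over-connected species in disease. Promotion interacts with the
abundance noise: only promoted species that also acquire high network
degree show the full connector signature, which is what the
ground-truth-recovery tests assert.

What the generator does **not** emulate: phylogenetic correlation between
related species, compositional negative correlation, longitudinal or
treatment effects, read-level noise. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted structure, not
that any particular real dataset has that structure.

## Problem sizes and tolerances in the shipped checks

The test suite exercises the pipeline at 120 species × 120 samples (module
recovery over 20 seeds; 50-run consensus), rich-club ensembles of 1000,
percolation with 10 replicates per group and 500 permutations — sizes at
which the stochastic summaries are stable while the whole suite runs in a
few minutes. Oracle equivalences are exact (motif census vs brute-force
enumeration), 1e-8 (power iteration vs dense eigendecomposition) or 1e-12
(Louvain vs exhaustive partition search at n ≤ 8, evaluated at
n_restarts = 10).

## Known limitations

* Weighted-network variants (weighted path metrics, weighted rich club) are
  out of scope; the analysis is intentionally binary after thresholding.
* The consensus construction is one of several in the literature; it shares
  the contract (stable partition + agreement statistics) but not
  necessarily the exact output of other implementations.
* Empirical p-values are bounded below by 1/(n+1); ensemble sizes bound the
  resolution of significance claims.
* The Ružička form is one specific abundance-weighted Jaccard; other
  weighted variants exist and would shift absolute similarity values
  (though thresholding is rank-adaptive).
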