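"""Modularity maximization, consensus partitions, and partition similarity.

Community structure is found by maximizing Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / (2m)] * delta(C_i, C_j)

with a Louvain-style locally greedy algorithm: nodes are swept in a
seeded random order, each moved to the neighbouring community with the
largest modularity gain, then communities are aggregated into supernodes and
the process repeats. Because the modularity landscape is nearly degenerate,
the optimization is repeated many times from different sweep orders and a
*consensus* partition is distilled: pairwise co-assignment frequencies are
collected into an agreement matrix, entries below the level expected from
randomly permuted partitions are zeroed, and the agreement graph is
re-clustered until all runs agree.

Partition similarity is measured by the (plain, unadjusted) Rand index —
the fraction of node pairs on which two partitions agree — with a label-
permutation null for significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import rand_score

from ._rng import seed_sequence
from .errors import ConvergenceError, InputError

__all__ = [
    "Partition",
    "ConsensusResult",
    "modularity",
    "louvain",
    "consensus",
    "rand_index",
    "rand_permutation_test",
]


@dataclass
class Partition:
    membership: dict            # node -> community id (0..K-1)
    Q: float
    gamma: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def labels_for(self, nodes) -> np.ndarray:
        return np.array([self.membership[u] for u in nodes])


def _membership_of(partition) -> dict:
    return partition.membership if isinstance(partition, Partition) else dict(partition)


def modularity(net: nx.Graph, partition, gamma: float = 1.0,
               weight: str = "weight") -> float:
    """Modularity Q of a partition (strengths = degrees on binary networks)."""
    membership = _membership_of(partition)
    missing = set(net.nodes) - set(membership)
    if missing:
        raise InputError(f"partition misses nodes: {sorted(missing)[:5]} ...")
    two_m = sum(d for _, d in net.degree(weight=weight))
    if two_m == 0:
        raise InputError("modularity is undefined on an edgeless network")
    sum_in = {}
    sum_tot = {}
    for u, k in net.degree(weight=weight):
        sum_tot[membership[u]] = sum_tot.get(membership[u], 0.0) + k
    for u, v, data in net.edges(data=True):
        if membership[u] == membership[v]:
            w = data.get(weight, 1.0)
            sum_in[membership[u]] = sum_in.get(membership[u], 0.0) + 2.0 * w
    q = 0.0
    for c, tot in sum_tot.items():
        q += sum_in.get(c, 0.0) / two_m - gamma * (tot / two_m) ** 2
    return q


# ---------------------------------------------------------------------------
# Louvain


def _louvain_level(adj, selfw, k, two_m, gamma, rng):
    """One level of local moves; returns (membership array, moved_any)."""
    n = len(k)
    comm = np.arange(n)
    comm_tot = k.copy()
    moved_any = False
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = comm[i]
            comm_tot[ci] -= k[i]
            links = {}
            for j, w in adj[i].items():
                links[comm[j]] = links.get(comm[j], 0.0) + w
            best_c, best_gain = ci, links.get(ci, 0.0) - gamma * comm_tot[ci] * k[i] / two_m
            for c, w_ic in links.items():
                if c == ci:
                    continue
                gain = w_ic - gamma * comm_tot[c] * k[i] / two_m
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            comm[i] = best_c
            comm_tot[best_c] += k[i]
            if best_c != ci:
                improved = True
                moved_any = True
    return comm, moved_any


def _aggregate(adj, selfw, comm):
    """Collapse communities into supernodes (A_cc holds 2x internal weight)."""
    labels = {c: i for i, c in enumerate(dict.fromkeys(comm.tolist()))}
    new_n = len(labels)
    new_adj = [dict() for _ in range(new_n)]
    new_self = np.zeros(new_n)
    for i, c in enumerate(comm):
        new_self[labels[c]] += selfw[i]
    for i in range(len(adj)):
        ci = labels[comm[i]]
        for j, w in adj[i].items():
            if j <= i:
                continue
            cj = labels[comm[j]]
            if ci == cj:
                new_self[ci] += 2.0 * w
            else:
                new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
    mapping = np.array([labels[c] for c in comm])
    return new_adj, new_self, mapping


def louvain(net: nx.Graph, gamma: float = 1.0, seed=None,
            weight: str = "weight", n_restarts: int = 1) -> Partition:
    """Seeded Louvain run; sweep order is the only stochastic element.

    With ``n_restarts > 1`` the algorithm is restarted from derived seeds and
    the highest-Q partition returned — the usual guard against the rare
    greedy collapse of a single run (the consensus machinery instead wants
    the run-to-run diversity of single starts, so the default is 1).
    """
    if net.number_of_edges() == 0:
        raise InputError("community detection needs at least one edge")
    if n_restarts < 1:
        raise InputError("n_restarts must be >= 1")
    if n_restarts > 1:
        runs = [louvain(net, gamma, s, weight)
                for s in seed_sequence(seed).spawn(n_restarts)]
        return max(runs, key=lambda p: p.Q)
    rng = np.random.default_rng(seed)
    nodes = list(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    adj = [dict() for _ in nodes]
    selfw = np.zeros(len(nodes))
    for u, v, data in net.edges(data=True):
        w = float(data.get(weight, 1.0))
        if u == v:
            selfw[index[u]] += 2.0 * w
        else:
            adj[index[u]][index[v]] = adj[index[u]].get(index[v], 0.0) + w
            adj[index[v]][index[u]] = adj[index[v]].get(index[u], 0.0) + w
    assignment = np.arange(len(nodes))
    while True:
        k = np.array([sum(a.values()) for a in adj]) + selfw
        two_m = k.sum()
        comm, moved = _louvain_level(adj, selfw, k, two_m, gamma, rng)
        if not moved:
            break
        adj, selfw, mapping = _aggregate(adj, selfw, comm)
        assignment = mapping[comm[assignment]]
        if len(adj) == 1:
            break
    # renumber communities by first appearance
    relabel = {}
    membership = {}
    for u in nodes:
        c = int(assignment[index[u]])
        membership[u] = relabel.setdefault(c, len(relabel))
    q = modularity(net, membership, gamma, weight)
    return Partition(membership=membership, Q=q, gamma=gamma)


# ---------------------------------------------------------------------------
# Consensus over repeated optimizations


@dataclass
class ConsensusResult:
    consensus_partition: Partition
    agreement: pd.DataFrame
    Q_mean: float
    Q_sd: float
    community_count_frequencies: dict
    n_runs: int
    n_consensus_iterations: int = 0


def _agreement_matrix(runs: list, nodes: list) -> np.ndarray:
    labels = np.array([[r.membership[u] for u in nodes] for r in runs])
    n = len(nodes)
    agree = np.zeros((n, n))
    for row in labels:
        agree += row[:, None] == row[None, :]
    agree /= len(runs)
    return agree


def _expected_coassignment(runs: list, n: int) -> float:
    """Mean pair co-assignment probability under random label permutation."""
    if n < 2:
        return 0.0
    exp = []
    for r in runs:
        sizes = np.bincount(np.array(list(r.membership.values())))
        exp.append((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    return float(np.mean(exp))


def consensus(net: nx.Graph, gamma: float = 1.0, n_runs: int = 1000, seed=None,
              max_consensus_iter: int = 50) -> ConsensusResult:
    """Repeated Louvain + agreement-matrix reclustering until runs agree."""
    if n_runs < 1:
        raise InputError("n_runs must be >= 1")
    nodes = sorted(net.nodes)
    streams = iter(seed_sequence(seed).spawn(n_runs * (max_consensus_iter + 1)))
    runs = [louvain(net, gamma, next(streams)) for _ in range(n_runs)]
    qs = np.array([r.Q for r in runs])
    counts = np.array([r.n_communities for r in runs])
    freq = {int(c): float(f) for c, f in
            zip(*np.unique(counts, return_counts=True))}
    freq = {c: f / n_runs for c, f in freq.items()}
    agreement = _agreement_matrix(runs, nodes)
    first_agreement = agreement.copy()
    tau = _expected_coassignment(runs, len(nodes))

    for iteration in range(1, max_consensus_iter + 1):
        if all(r.membership == runs[0].membership for r in runs[1:]):
            final = runs[0]
            return ConsensusResult(
                consensus_partition=Partition(final.membership,
                                              modularity(net, final.membership, gamma),
                                              gamma),
                agreement=pd.DataFrame(first_agreement, index=nodes, columns=nodes),
                Q_mean=float(qs.mean()), Q_sd=float(qs.std(ddof=0)),
                community_count_frequencies=freq, n_runs=n_runs,
                n_consensus_iterations=iteration - 1)
        thresholded = np.where(agreement > tau, agreement, 0.0)
        np.fill_diagonal(thresholded, 0.0)
        graph = nx.Graph()
        graph.add_nodes_from(range(len(nodes)))
        iu, ju = np.nonzero(np.triu(thresholded, k=1))
        graph.add_weighted_edges_from(
            (int(i), int(j), float(thresholded[i, j])) for i, j in zip(iu, ju))
        if graph.number_of_edges() == 0:
            singleton = {u: i for i, u in enumerate(nodes)}
            runs = [Partition(singleton, 0.0, gamma)] * n_runs
            continue
        runs = [
            Partition({nodes[i]: c for i, c in
                       louvain(graph, gamma, next(streams)).membership.items()},
                      0.0, gamma)
            for _ in range(n_runs)
        ]
        agreement = _agreement_matrix(runs, nodes)
    raise ConvergenceError(
        f"consensus did not stabilize in {max_consensus_iter} iterations")


# ---------------------------------------------------------------------------
# Partition similarity


def rand_index(p1, p2) -> float:
    """Plain Rand index: fraction of node pairs on which the partitions agree."""
    m1, m2 = _membership_of(p1), _membership_of(p2)
    if set(m1) != set(m2):
        raise InputError("partitions cover different node sets")
    nodes = sorted(m1)
    return float(rand_score([m1[u] for u in nodes], [m2[u] for u in nodes]))


def rand_permutation_test(p1, p2, n_perm: int = 1000, seed=None) -> dict:
    """One-sided label-permutation test of partition similarity.

    The null permutes which node carries which label in the second partition
    (block sizes preserved); p = (1 + #{null >= observed}) / (n_perm + 1).
    A single-community partition makes the null degenerate (flagged: every
    permuted Rand equals the observed one).
    """
    if n_perm < 100:
        raise InputError("n_perm must be >= 100")
    m1, m2 = _membership_of(p1), _membership_of(p2)
    if set(m1) != set(m2):
        raise InputError("partitions cover different node sets")
    nodes = sorted(m1)
    a = np.array([m1[u] for u in nodes])
    b = np.array([m2[u] for u in nodes])
    observed = float(rand_score(a, b))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = rand_score(a, rng.permutation(b))
    p = (1 + (null >= observed - 1e-12).sum()) / (n_perm + 1)
    return {
        "observed": observed,
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=0)),
        "p": float(p),
        "degenerate": len(set(a.tolist())) == 1 or len(set(b.tolist())) == 1,
    }
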