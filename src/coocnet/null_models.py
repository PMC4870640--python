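"""Benchmark null models: degree-preserving rewiring, lattices, metric audit.

The degree-preserving null randomizes edges by repeated double-edge swaps
(Maslov–Sneppen): pick two edges (u,v), (x,y) and replace them with (u,x),
(v,y), rejecting any swap that would create a self-loop or a multi-edge.
Every node's degree is conserved exactly. The lattice benchmark is a ring
lattice built deterministically by node index.

Because the underlying similarity 1 - J is a true metric, the observed
network's weighted triangles satisfy the triangle inequality by
construction; rewired nulls need not. ``triangle_violation_rate`` audits how
often d(i,k) > d(i,j) + d(j,k) over node triplets of a (possibly
null-weighted) similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import seed_sequence
from .errors import InputError

__all__ = [
    "NetworkEnsemble",
    "rewire_degree_preserving",
    "make_ensemble",
    "make_lattice",
    "assign_null_weights",
    "triangle_violation_rate",
    "ensemble_violation_rate",
]

DEFAULT_SWAPS_PER_EDGE = 10


@dataclass
class NetworkEnsemble:
    members: list
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


def rewire_degree_preserving(net: nx.Graph, n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
                             seed=None) -> nx.Graph:
    """Degree-preserving randomization by attempted double-edge swaps.

    Attempts ``n_swaps_per_edge * |E|`` swaps. If no legal swap succeeds
    (e.g. a complete graph), the input is returned unchanged with
    ``graph["rewire_warning"] = True``.
    """
    if net.number_of_edges() < 2:
        raise InputError("need at least 2 edges to rewire")
    rng = np.random.default_rng(seed)
    nodes = list(net.nodes)
    edges = [tuple(e) for e in net.edges]
    adj = {n: set(net[n]) for n in nodes}
    m = len(edges)
    successes = 0
    for _ in range(n_swaps_per_edge * m):
        i, j = rng.integers(m), rng.integers(m)
        if i == j:
            continue
        u, v = edges[i]
        x, y = edges[j]
        if rng.random() < 0.5:
            x, y = y, x
        # proposed replacement: (u,x) and (v,y)
        if len({u, v, x, y}) < 4:
            continue
        if x in adj[u] or y in adj[v]:
            continue
        adj[u].remove(v); adj[v].remove(u)
        adj[x].remove(y); adj[y].remove(x)
        adj[u].add(x); adj[x].add(u)
        adj[v].add(y); adj[y].add(v)
        edges[i], edges[j] = (u, x), (v, y)
        successes += 1
    out = nx.Graph()
    out.add_nodes_from(nodes)
    out.add_edges_from(edges)
    if successes == 0:
        out.graph["rewire_warning"] = True
    return out


def make_ensemble(net: nx.Graph, size: int, seed=None,
                  n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE) -> NetworkEnsemble:
    """Ensemble of independently rewired replicates with derived seeds."""
    if size < 1:
        raise InputError("ensemble size must be >= 1")
    streams = seed_sequence(seed).spawn(size)
    members = [rewire_degree_preserving(net, n_swaps_per_edge, s) for s in streams]
    return NetworkEnsemble(members, provenance={
        "generator": "degree_preserving_rewire",
        "size": size,
        "seed": seed,
        "n_swaps_per_edge": n_swaps_per_edge,
        "source_n_nodes": net.number_of_nodes(),
        "source_n_edges": net.number_of_edges(),
    })


def make_lattice(n_nodes: int, n_edges: int) -> nx.Graph:
    """Ring lattice with exactly ``n_edges`` edges.

    Nearest-neighbour rings (offset 1, then 2, ...) are filled in order; the
    outermost partial ring is placed deterministically by node index.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise InputError(f"cannot place {n_edges} edges on {n_nodes} nodes")
    net = nx.Graph()
    net.add_nodes_from(range(n_nodes))
    budget = n_edges
    for offset in range(1, n_nodes // 2 + 1):
        if budget == 0:
            break
        for i in range(n_nodes):
            if budget == 0:
                break
            j = (i + offset) % n_nodes
            if not net.has_edge(i, j):
                net.add_edge(i, j)
                budget -= 1
    return net


def assign_null_weights(rewired: nx.Graph, source: nx.Graph, sim: pd.DataFrame,
                        seed=None) -> pd.DataFrame:
    """Similarity matrix for a binary null network.

    The source network's retained similarity values are permuted onto the
    rewired edges; non-edges get similarity 0, the diagonal 1. This gives a
    weighted object on which the triangle audit is defined.
    """
    rng = np.random.default_rng(seed)
    retained = np.array([sim.loc[u, v] for u, v in source.edges])
    if len(retained) != rewired.number_of_edges():
        raise InputError("rewired network must have the source's edge count")
    perm = rng.permutation(retained)
    labels = list(rewired.nodes)
    pos = {n: i for i, n in enumerate(labels)}
    J = np.zeros((len(labels), len(labels)))
    for w, (u, v) in zip(perm, rewired.edges):
        J[pos[u], pos[v]] = J[pos[v], pos[u]] = w
    np.fill_diagonal(J, 1.0)
    return pd.DataFrame(J, index=labels, columns=labels)


def triangle_violation_rate(sim: pd.DataFrame, atol: float = 1e-12) -> tuple[float, float]:
    """Fraction of node triplets violating the triangle inequality on 1 - J.

    A triplet {i, j, k} violates iff its longest side exceeds the sum of the
    other two (checked with a small absolute tolerance so exact-metric inputs
    are not flagged by rounding). Returns ``(fraction, binomial_se)``.
    """
    n = len(sim)
    if n < 3:
        raise InputError("need at least 3 nodes for a triplet audit")
    d = 1.0 - sim.to_numpy(dtype=float)
    violations = 0
    total = n * (n - 1) * (n - 2) // 6
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            a = d[i, j]
            b = d[i, j + 1:]
            c = d[j, j + 1:]
            s = a + b + c
            mx = np.maximum(a, np.maximum(b, c))
            violations += int((2 * mx > s + atol).sum())
    frac = violations / total
    se = float(np.sqrt(frac * (1 - frac) / total))
    return frac, se


def ensemble_violation_rate(source: nx.Graph, sim: pd.DataFrame, size: int = 100,
                            seed=None,
                            n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE) -> tuple[float, float]:
    """Mean +/- sd of the triangle-violation rate across a rewired ensemble."""
    streams = seed_sequence(seed).spawn(2 * size)
    rates = []
    for k in range(size):
        null = rewire_degree_preserving(source, n_swaps_per_edge, streams[2 * k])
        null_sim = assign_null_weights(null, source, sim, streams[2 * k + 1])
        rates.append(triangle_violation_rate(null_sim)[0])
    return float(np.mean(rates)), float(np.std(rates, ddof=0))
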