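"""Abundance-weighted Jaccard similarity and network thresholding.

The pipeline's first analytic stage: turn a species × sample abundance table
into (i) a weighted similarity matrix and (ii) a binary, undirected
co-occurrence network.  Similarity between two species' abundance profiles
x, y across samples is the abundance-weighted (Ruzicka) Jaccard index

    J(x, y) = sum_s min(x_s, y_s) / sum_s max(x_s, y_s),

which is 1 for perfectly overlapping profiles and 0 when the species never
co-occur, and keeps the influence of relative abundance rather than reducing
profiles to presence/absence.  The network keeps an edge wherever the
similarity exceeds the off-diagonal mean by more than ``multiplier`` standard
deviations (default one), a data-adaptive cut that retains roughly the
strongest fifth of co-occurrences on realistically sparse tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy.spatial.distance import pdist, squareform

from .errors import InputError

__all__ = [
    "weighted_jaccard",
    "threshold_network",
    "prune_isolated",
    "harmonize_species_sets",
    "build_network",
    "threshold_sweep",
]


def weighted_jaccard(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise abundance-weighted Jaccard similarity between species rows.

    Uses the identity sum(min) = (|x|_1 + |y|_1 - |x - y|_1)/2 (valid for
    non-negative profiles) so the whole matrix reduces to one Manhattan
    ``pdist`` call. Pairs of all-zero profiles score 0 by convention; the
    diagonal is defined as 1.
    """
    if table.empty:
        raise InputError("empty abundance table")
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise InputError("negative abundances are not allowed")
    s = X.sum(axis=1)
    D = squareform(pdist(X, metric="cityblock")) if len(X) > 1 else np.zeros((1, 1))
    tot = s[:, None] + s[None, :]
    denom = tot + D
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(denom > 0, (tot - D) / np.where(denom > 0, denom, 1.0), 0.0)
    np.clip(J, 0.0, 1.0, out=J)  # guard against float round-off at the bounds
    np.fill_diagonal(J, 1.0)
    return pd.DataFrame(J, index=table.index, columns=table.index)


def similarity_cutoff(sim: pd.DataFrame, multiplier: float = 1.0) -> float:
    """mean + multiplier * sd of the off-diagonal upper-triangle entries.

    The population standard deviation is used, and zero similarities are
    included — they are real observations of non-co-occurrence and dilute the
    mean, which is what makes the one-sd rule select only the strong tail.
    """
    J = sim.to_numpy(dtype=float)
    iu = np.triu_indices_from(J, k=1)
    vals = J[iu]
    return float(vals.mean() + multiplier * vals.std(ddof=0))


def threshold_network(sim: pd.DataFrame, multiplier: float = 1.0) -> nx.Graph:
    """Binarize a similarity matrix into an undirected co-occurrence network.

    Keeps edge (i, j) iff J_ij is *strictly* greater than the cutoff
    ``mean + multiplier * sd``; ties at the cutoff are excluded.
    All species stay as nodes (possibly isolated) so that pruning is an
    explicit, recorded step.
    """
    if len(sim) < 2:
        raise InputError("need at least 2 species to threshold")
    labels = list(sim.index)
    J = sim.to_numpy(dtype=float)
    cutoff = similarity_cutoff(sim, multiplier)
    net = nx.Graph()
    net.add_nodes_from(labels)
    iu, ju = np.where(np.triu(J, k=1) > cutoff)
    net.add_edges_from((labels[i], labels[j]) for i, j in zip(iu, ju))
    net.graph["cutoff"] = cutoff
    net.graph["threshold_multiplier"] = multiplier
    return net


def prune_isolated(net: nx.Graph) -> tuple[nx.Graph, list]:
    """Drop degree-0 nodes; returns ``(pruned_copy, removed_labels)``."""
    removed = sorted(nx.isolates(net))
    pruned = net.copy()
    pruned.remove_nodes_from(removed)
    return pruned, removed


def harmonize_species_sets(net_a: nx.Graph, net_b: nx.Graph) -> tuple[nx.Graph, nx.Graph]:
    """Re-index two cohort networks on the union of their non-isolated species.

    A species is kept if it maintains at least one connection in at least one
    network; it then appears in both (with degree 0 where it had no edges).
    """
    if not set(net_a) & set(net_b):
        raise InputError("networks share no species labels")
    keep = ({n for n, d in net_a.degree if d > 0}
            | {n for n, d in net_b.degree if d > 0})

    def reindex(net: nx.Graph) -> nx.Graph:
        out = nx.Graph()
        out.graph.update(net.graph)
        out.add_nodes_from(sorted(keep))
        out.add_edges_from((u, v) for u, v in net.edges if u in keep and v in keep)
        return out

    return reindex(net_a), reindex(net_b)


def build_network(table: pd.DataFrame, multiplier: float = 1.0,
                  prune: bool = True) -> tuple[nx.Graph, list]:
    """Abundance table -> pruned co-occurrence network (convenience wrapper)."""
    sim = weighted_jaccard(table)
    net = threshold_network(sim, multiplier)
    if prune:
        return prune_isolated(net)
    return net, []


def threshold_sweep(table: pd.DataFrame, multipliers=(0.5, 1.0, 1.5)) -> pd.DataFrame:
    """Global-metric sensitivity table across threshold multipliers.

    Robustness harness for the data-adaptive cut: rerun the global metrics at
    each multiplier and report them side by side.
    """
    from .graph_core import global_metrics

    sim = weighted_jaccard(table)
    rows = []
    for m in multipliers:
        net, removed = prune_isolated(threshold_network(sim, m))
        gm = global_metrics(net)
        row = {"multiplier": m, "n_removed": len(removed)}
        row.update(gm.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("multiplier")
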