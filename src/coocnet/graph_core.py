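"""Global network measures: clustering, path length, efficiency, diameter.

Conventions for fragmenting graphs (these matter under percolation):

* nodes of degree < 2 contribute a clustering coefficient of 0 and *are*
  included in the average;
* the characteristic path length PL averages shortest-path distances over
  connected pairs only (NaN when there are none);
* global efficiency E averages 1/d over *all* ordered pairs with 1/inf = 0,
  so it is well defined on any graph;
* the diameter is the longest finite shortest path, i.e. the diameter of the
  largest connected component (0 for edgeless graphs).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .errors import InputError

__all__ = ["GlobalMetrics", "clustering_coefficient", "path_metrics", "global_metrics"]


@dataclass(frozen=True)
class GlobalMetrics:
    C: float
    PL: float
    E: float
    diameter: float
    n_nodes: int
    n_edges: int

    def to_dict(self) -> dict:
        return {"C": self.C, "PL": self.PL, "E": self.E,
                "diameter": self.diameter, "n_nodes": self.n_nodes,
                "n_edges": self.n_edges}


def clustering_coefficient(net: nx.Graph) -> tuple[dict, float]:
    """Per-node local clustering and its average over all nodes."""
    if net.number_of_nodes() == 0:
        raise InputError("empty network")
    per_node = nx.clustering(net)
    return per_node, float(np.mean(list(per_node.values())))


def _distance_matrix(net: nx.Graph) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(net, format="csr", dtype=float)
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def path_metrics(net: nx.Graph) -> tuple[float, float, float]:
    """Return ``(PL, E, diameter)`` under the conventions above."""
    n = net.number_of_nodes()
    if n == 0:
        raise InputError("empty network")
    if n == 1:
        return float("nan"), 0.0, 0.0
    d = _distance_matrix(net)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if finite.any():
        pl = float(d[finite].mean())
        diameter = float(d[finite].max())
    else:
        pl, diameter = float("nan"), 0.0
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    e = float(inv[off].sum() / (n * (n - 1)))
    return pl, e, diameter


def global_metrics(net: nx.Graph) -> GlobalMetrics:
    """One-call bundle of the global measures."""
    _, c = clustering_coefficient(net)
    pl, e, diameter = path_metrics(net)
    return GlobalMetrics(C=c, PL=pl, E=e, diameter=diameter,
                         n_nodes=net.number_of_nodes(),
                         n_edges=net.number_of_edges())
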