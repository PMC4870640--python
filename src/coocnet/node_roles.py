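"""Node roles within community structure: intra-module Z and participation P.

For node i in module s_i:

    Z_i = (a_i_intra - mean_s) / sigma_s      (population sd over the module)
    P_i = 1 - sum_s (a_is / a_i)^2

Z measures how strongly a node is wired into its own module relative to its
module mates; P measures how evenly its edges spread across modules (0 when
all edges are intra-modular, approaching 1 - 1/K for an even spread over K
modules). Nodes are tiled into six roles by Z > 0 vs Z <= 0 crossed with
P < 0.2 (provincial), 0.2 <= P < 0.55 (peripheral) and P >= 0.55 (connector);
boundary values are assigned to the higher-P tile. Inter-module connections
are also reported as absolute counts, which avoids spurious high-P calls on
low-degree nodes.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .communities import _membership_of
from .errors import InputError

__all__ = ["role_profile", "assign_roles", "role_shift_table", "ROLE_NAMES"]

P_LOW, P_HIGH = 0.2, 0.55
ROLE_NAMES = (
    "provincial hub", "peripheral hub", "connector hub",
    "provincial non-hub", "peripheral non-hub", "connector non-hub",
)


def assign_roles(z: float, p: float) -> str:
    """Role tile for one (Z, P) pair; boundaries go to the higher-P tile."""
    hub = "hub" if z > 0 else "non-hub"
    if p < P_LOW:
        band = "provincial"
    elif p < P_HIGH:
        band = "peripheral"
    else:
        band = "connector"
    return f"{band} {hub}"


def role_profile(net: nx.Graph, partition) -> pd.DataFrame:
    """Per-node role table: degrees, intra degree, Z, P, role tile.

    Modules of size 1 or with zero intra-degree spread get Z = 0, flagged in
    the ``z_degenerate`` column. Isolated nodes get P = 0 by convention.
    """
    membership = _membership_of(partition)
    missing = set(net.nodes) - set(membership)
    if missing:
        raise InputError(f"partition misses nodes: {sorted(missing)[:5]} ...")
    nodes = sorted(net.nodes)
    own = {u: membership[u] for u in nodes}
    per_module_deg = {}
    intra = {}
    for u in nodes:
        counts = {}
        for v in net[u]:
            counts[membership[v]] = counts.get(membership[v], 0) + 1
        per_module_deg[u] = counts
        intra[u] = counts.get(own[u], 0)

    # intra-degree statistics within each module
    stats = {}
    for mod in set(own.values()):
        vals = np.array([intra[u] for u in nodes if own[u] == mod], dtype=float)
        stats[mod] = (vals.mean(), vals.std(ddof=0), len(vals))

    rows = []
    for u in nodes:
        a_i = net.degree[u]
        mean_s, sd_s, size_s = stats[own[u]]
        degenerate = size_s < 2 or sd_s == 0
        z = 0.0 if degenerate else (intra[u] - mean_s) / sd_s
        if a_i == 0:
            p = 0.0
        else:
            p = 1.0 - sum((c / a_i) ** 2 for c in per_module_deg[u].values())
        rows.append({
            "module": own[u], "degree": a_i, "intra_degree": intra[u],
            "inter_degree": a_i - intra[u], "Z": z, "P": p,
            "z_degenerate": degenerate, "role": assign_roles(z, p),
        })
    return pd.DataFrame(rows, index=pd.Index(nodes, name="species"))


def role_shift_table(profiles_a: pd.DataFrame, profiles_b: pd.DataFrame) -> pd.DataFrame:
    """Joint per-species role table for two cohorts, sorted by P shift.

    Species absent from one profile are recorded with the sentinel role
    ``"isolated"`` (P = 0, Z = 0, no connections) rather than dropped.
    """
    union = profiles_a.index.union(profiles_b.index)

    def col(profiles, name, fill):
        return profiles[name].reindex(union, fill_value=fill)

    out = pd.DataFrame({
        "role_a": col(profiles_a, "role", "isolated"),
        "role_b": col(profiles_b, "role", "isolated"),
        "P_a": col(profiles_a, "P", 0.0),
        "P_b": col(profiles_b, "P", 0.0),
        "Z_a": col(profiles_a, "Z", 0.0),
        "Z_b": col(profiles_b, "Z", 0.0),
        "inter_a": col(profiles_a, "inter_degree", 0),
        "inter_b": col(profiles_b, "inter_degree", 0),
    })
    out["dP"] = out["P_b"] - out["P_a"]
    out["dZ"] = out["Z_b"] - out["Z_a"]
    out["d_inter"] = out["inter_b"] - out["inter_a"]
    out.index.name = "species"
    return out.sort_values("dP", ascending=False)
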