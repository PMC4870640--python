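"""Rich-club curves, null normalization, and functional curve comparison.

For each degree threshold k (0 .. max_degree - 1), remove every node whose
degree in the *original* network is <= k; the rich-club coefficient is the
edge density of what remains:

    phi(k) = E_>k / (n_k * (n_k - 1) / 2),

undefined (masked) when fewer than two nodes survive. Raw curves are hard to
read because even degree-matched random graphs show rising phi(k), so phi is
normalized by the mean curve of a degree-preserving rewired ensemble:
phi_norm(k) = phi(k) / mean_r phi_r(k), with a one-sided per-k empirical p
(the pseudo-counted fraction of null curves at or above the observed one).
phi_norm(k) > 1 at high k is the signature of a rich club.

Two networks' normalized curves are compared with a functional permutation
test: the per-replicate normalized curves are the repeated observations;
group labels are shuffled and the per-k difference of group means is
re-computed to build the null.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["RichClubCurve", "rich_club_curve", "normalized_rich_club", "compare_curves"]


@dataclass
class RichClubCurve:
    table: pd.DataFrame            # k, phi, phi_random, phi_norm, p, evaluable
    replicate_norm: np.ndarray     # (n_members, n_k) per-replicate phi/phi_r
    provenance: dict

    @property
    def k(self) -> np.ndarray:
        return self.table.index.to_numpy()


def _phi_values(degrees: np.ndarray, edges: list, k_max: int) -> np.ndarray:
    """phi(k) for k = 0..k_max-1 via incremental node removal; NaN = masked."""
    n = len(degrees)
    alive = np.ones(n, dtype=bool)
    adj = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    e_rem = len(edges)
    n_rem = n
    order = np.argsort(degrees, kind="stable")
    phi = np.full(k_max, np.nan)
    ptr = 0
    for k in range(k_max):
        while ptr < n and degrees[order[ptr]] <= k:
            v = order[ptr]
            alive[v] = False
            e_rem -= sum(1 for u in adj[v] if alive[u])
            n_rem -= 1
            ptr += 1
        if n_rem >= 2:
            phi[k] = e_rem / (n_rem * (n_rem - 1) / 2)
    return phi


def rich_club_curve(net: nx.Graph) -> pd.DataFrame:
    """Raw phi(k) table for k from 0 to max_degree - 1."""
    if net.number_of_edges() == 0:
        raise InputError("rich-club curve needs at least one edge")
    nodes = list(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    degrees = np.array([net.degree[u] for u in nodes])
    edges = [(index[u], index[v]) for u, v in net.edges]
    k_max = int(degrees.max())
    phi = _phi_values(degrees, edges, k_max)
    return pd.DataFrame({"phi": phi}, index=pd.Index(range(k_max), name="k"))


def normalized_rich_club(net: nx.Graph, ensemble) -> RichClubCurve:
    """Null-normalized rich-club curve with per-k one-sided empirical p."""
    members = list(ensemble)
    if not members:
        raise InputError("empty ensemble")
    real = rich_club_curve(net)["phi"].to_numpy()
    k_max = len(real)
    null = np.full((len(members), k_max), np.nan)
    for r, g in enumerate(members):
        phi_r = rich_club_curve(g)["phi"].to_numpy()
        null[r, : min(k_max, len(phi_r))] = phi_r[:k_max]
    n_valid_rows = np.isfinite(null).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        null_mean = np.where(n_valid_rows > 0,
                             np.nansum(null, axis=0) / np.maximum(n_valid_rows, 1),
                             np.nan)
        evaluable = np.isfinite(real) & np.isfinite(null_mean) & (null_mean > 0)
        phi_norm = np.where(evaluable, real / np.where(evaluable, null_mean, 1.0), np.nan)
        replicate_norm = np.where(null > 0, real[None, :] / np.where(null > 0, null, 1.0), np.nan)
    exceed = np.nansum(null >= real[None, :] - 1e-12, axis=0)
    n_valid = np.isfinite(null).sum(axis=0)
    p = np.where(evaluable & (n_valid > 0), (1 + exceed) / (n_valid + 1), np.nan)
    table = pd.DataFrame({
        "phi": real, "phi_random": null_mean, "phi_norm": phi_norm,
        "p": p, "evaluable": evaluable,
    }, index=pd.Index(range(k_max), name="k"))
    prov = dict(getattr(ensemble, "provenance", {}))
    return RichClubCurve(table=table, replicate_norm=replicate_norm, provenance=prov)


def compare_curves(curve_a: RichClubCurve, curve_b: RichClubCurve,
                   n_perm: int = 1000, seed=None) -> pd.DataFrame:
    """Functional permutation comparison of two normalized rich-club curves.

    Per evaluable k: observed difference phi_norm_A - phi_norm_B, the null
    mean and sd of the difference of group means under label shuffling of the
    pooled per-replicate normalized curves, and one-sided p in each direction.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    eval_a = curve_a.table["evaluable"].to_numpy()
    eval_b = curve_b.table["evaluable"].to_numpy()
    k_common = min(len(eval_a), len(eval_b))
    mask = eval_a[:k_common] & eval_b[:k_common]
    if not mask.any():
        raise InputError("curves share no evaluable degree range")
    ks = np.nonzero(mask)[0]
    rep_a = curve_a.replicate_norm[:, ks]
    rep_b = curve_b.replicate_norm[:, ks]
    obs = (curve_a.table["phi_norm"].to_numpy()[ks]
           - curve_b.table["phi_norm"].to_numpy()[ks])
    pooled = np.vstack([rep_a, rep_b])
    n_a = rep_a.shape[0]
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(ks)))
    for i in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        null[i] = (np.nanmean(pooled[perm[:n_a]], axis=0)
                   - np.nanmean(pooled[perm[n_a:]], axis=0))
    p_a_gt = (1 + (null >= obs[None, :] - 1e-12).sum(axis=0)) / (n_perm + 1)
    p_b_gt = (1 + (null <= obs[None, :] + 1e-12).sum(axis=0)) / (n_perm + 1)
    return pd.DataFrame({
        "difference": obs,
        "null_mean": null.mean(axis=0),
        "null_sd": null.std(axis=0, ddof=0),
        "p_a_greater": p_a_gt,
        "p_b_greater": p_b_gt,
    }, index=pd.Index(ks, name="k"))
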