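"""Plain-text serialization: abundance tables, matrices, edge lists, partitions."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import InputError

__all__ = [
    "read_abundance", "write_abundance",
    "read_similarity", "write_similarity",
    "read_edgelist", "write_edgelist",
    "read_partition", "write_partition",
    "write_json", "read_json",
]


def read_abundance(path) -> pd.DataFrame:
    """Species × sample TSV: first column species labels, header = sample IDs."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.empty:
        raise InputError(f"empty abundance table: {path}")
    if (table.to_numpy() < 0).any():
        raise InputError(f"negative abundances in {path}")
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise InputError(f"duplicate species or sample labels in {path}")
    table.index.name = "species"
    return table


def write_abundance(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_similarity(path) -> pd.DataFrame:
    sim = pd.read_csv(path, sep="\t", index_col=0)
    sim.columns = sim.columns.astype(sim.index.dtype, errors="ignore")
    return sim


def write_similarity(sim: pd.DataFrame, path) -> None:
    sim.to_csv(path, sep="\t")


def read_edgelist(path, nodes=None) -> nx.Graph:
    """Two-column TSV of species labels; optional full node universe."""
    net = nx.Graph()
    if nodes is not None:
        net.add_nodes_from(nodes)
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise InputError(f"edge list needs two columns: {path}")
    for u, v in frame.iloc[:, :2].itertuples(index=False):
        net.add_edge(u, v)
    return net


def write_edgelist(net: nx.Graph, path) -> None:
    pd.DataFrame(sorted(tuple(sorted(e)) for e in net.edges),
                 columns=["species_a", "species_b"]).to_csv(path, sep="\t", index=False)


def read_partition(path) -> dict:
    frame = pd.read_csv(path, sep="\t")
    return dict(zip(frame.iloc[:, 0], frame.iloc[:, 1]))


def write_partition(membership: dict, path) -> None:
    pd.DataFrame(sorted(membership.items()),
                 columns=["species", "community"]).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
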