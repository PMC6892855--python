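"""Serialization of fitted networks: adjacency CSV, edge list, GraphML."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .communities import Partition
from .estimation import IsingNetwork

_FLOAT_FMT = "%.10g"  # pinned so identical runs produce identical bytes


def network_frame(net: IsingNetwork) -> pd.DataFrame:
    return pd.DataFrame(net.weights, index=net.nodes, columns=net.nodes)


def edge_list(net: IsingNetwork) -> pd.DataFrame:
    rows = []
    for i, j in zip(*np.triu_indices(net.n_nodes, 1)):
        if net.weights[i, j] != 0:
            rows.append(
                {"node_i": net.nodes[i], "node_j": net.nodes[j],
                 "weight": net.weights[i, j]}
            )
    return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])


def to_networkx(net: IsingNetwork, partition: Partition | None = None) -> nx.Graph:
    g = nx.Graph()
    for i, name in enumerate(net.nodes):
        attrs = {"intercept": float(net.intercepts[i])}
        if partition is not None:
            attrs["community"] = int(partition.membership[i])
        g.add_node(name, **attrs)
    for i, j in zip(*np.triu_indices(net.n_nodes, 1)):
        if net.weights[i, j] != 0:
            g.add_edge(net.nodes[i], net.nodes[j], weight=float(net.weights[i, j]))
    return g


def write_network(
    net: IsingNetwork,
    directory: str | Path,
    stem: str,
    partition: Partition | None = None,
) -> None:
    """Write <stem>_adjacency.csv, <stem>_edges.csv, <stem>.graphml and
    <stem>_meta.json under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    network_frame(net).to_csv(directory / f"{stem}_adjacency.csv",
                              float_format=_FLOAT_FMT)
    edge_list(net).to_csv(directory / f"{stem}_edges.csv", index=False,
                          float_format=_FLOAT_FMT)
    nx.write_graphml(to_networkx(net, partition), directory / f"{stem}.graphml")
    meta = {
        "n_fit": net.n_fit,
        "gamma": net.gamma,
        "rule": net.rule,
        "dropped_nodes": net.dropped,
        "nodes": net.nodes,
    }
    (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))


def read_network(directory: str | Path, stem: str) -> IsingNetwork:
    directory = Path(directory)
    adj = pd.read_csv(directory / f"{stem}_adjacency.csv", index_col=0)
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    return IsingNetwork(
        weights=adj.to_numpy(dtype=float),
        intercepts=np.zeros(adj.shape[0]),
        nodes=list(adj.columns),
        n_fit=meta["n_fit"],
        gamma=meta["gamma"],
        rule=meta["rule"],
        dropped=meta["dropped_nodes"],
    )
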