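"""Modularity-based community detection on symptom networks.

Two algorithms guard against method idiosyncrasy: walktrap (agglomerative,
random-walk distances; igraph's implementation) and Girvan-Newman
edge-betweenness (divisive; implemented here so that betweenness can use
the 1/weight distance transform while modularity stays on the original
weights).  Both return the cut of their merge/removal sequence that
maximizes Newman's weighted modularity

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j).

Estimated Ising edge weights may be negative, where modularity is
undefined; both algorithms and the modularity function therefore consume
absolute weights.  Q = 0 for the all-in-one partition on every input, and
values above ~0.30 are conventionally read as clear community structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .estimation import IsingNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Partition:
    nodes: list[str]
    membership: np.ndarray       # community id per node
    modularity_q: float
    algorithm: str
    parameters: dict = field(default_factory=dict)

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.tolist()))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.nodes, (int(c) for c in self.membership)))


def _abs_weights(net: IsingNetwork | np.ndarray) -> np.ndarray:
    w = net.weights if isinstance(net, IsingNetwork) else np.asarray(net, dtype=float)
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    return np.abs(w)


def _node_names(net, p: int) -> list[str]:
    if isinstance(net, IsingNetwork):
        return list(net.nodes)
    return [f"V{i + 1}" for i in range(p)]


def _canonical_membership(membership: np.ndarray) -> np.ndarray:
    """Relabel communities by first appearance so output is order-stable."""
    mapping: dict[int, int] = {}
    out = np.empty(len(membership), dtype=np.int64)
    for i, c in enumerate(membership):
        if c not in mapping:
            mapping[c] = len(mapping)
        out[i] = mapping[c]
    return out


def modularity(net: IsingNetwork | np.ndarray, membership) -> float:
    """Weighted Newman modularity of a partition (on absolute weights).

    An all-zero network has no community structure by construction; Q is
    defined as 0 with a warning.
    """
    a = _abs_weights(net)
    membership = np.asarray(membership)
    if membership.shape[0] != a.shape[0]:
        raise ValueError("partition must cover all nodes")
    two_m = a.sum()
    if two_m == 0:
        warnings.warn("all-zero network: no division into subnetworks exists (Q = 0)",
                      stacklevel=2)
        return 0.0
    k = a.sum(axis=1)
    same = membership[:, None] == membership[None, :]
    q = ((a - np.outer(k, k) / two_m)[same]).sum() / two_m
    return float(q)


def _trivial_partition(net, p: int, algorithm: str, params: dict) -> Partition:
    return Partition(
        nodes=_node_names(net, p),
        membership=np.zeros(p, dtype=np.int64),
        modularity_q=0.0,
        algorithm=algorithm,
        parameters=params,
    )


def walktrap_communities(
    net: IsingNetwork | np.ndarray,
    walk_length: int = 4,
    exhaustive_check: bool = False,
) -> Partition:
    """Walktrap partition at the modularity-maximizing cut of the merge tree.

    Deterministic for fixed input.  With ``exhaustive_check`` (p <= 10)
    the gap to the exhaustive-search maximum is recorded in
    ``parameters['exhaustive_gap']``.
    """
    a = _abs_weights(net)
    p = a.shape[0]
    params: dict = {"walk_length": walk_length}
    if a.sum() == 0:
        return _trivial_partition(net, p, "walktrap", params)
    g = ig.Graph.Weighted_Adjacency(a.tolist(), mode="undirected", attr="weight")
    dendro = g.community_walktrap(weights="weight", steps=walk_length)
    clustering = dendro.as_clustering()  # cut maximizing modularity
    membership = _canonical_membership(np.asarray(clustering.membership))
    q = modularity(a, membership)
    if exhaustive_check:
        best_q, _ = exhaustive_best_partition(a)
        params["exhaustive_gap"] = best_q - q
    return Partition(_node_names(net, p), membership, q, "walktrap", params)


def _components_membership(g: nx.Graph, nodes: list[int]) -> np.ndarray:
    comp_of = {}
    for cid, comp in enumerate(sorted(nx.connected_components(g), key=min)):
        for v in comp:
            comp_of[v] = cid
    return np.array([comp_of[v] for v in nodes], dtype=np.int64)


def edge_betweenness_communities(
    net: IsingNetwork | np.ndarray,
    exhaustive_check: bool = False,
) -> Partition:
    """Girvan-Newman partition at the modularity-maximizing removal stage.

    Betweenness is computed on distances 1/weight (strong edges are
    short); modularity on the original absolute weights.  Ties in maximal
    betweenness break lexicographically on the sorted node pair, and ties
    in modularity keep the earliest (coarsest) stage, making runs
    bit-reproducible.
    """
    a = _abs_weights(net)
    p = a.shape[0]
    params: dict = {"distance_transform": "1/weight"}
    if a.sum() == 0:
        return _trivial_partition(net, p, "edge_betweenness", params)
    g = nx.Graph()
    g.add_nodes_from(range(p))
    for i in range(p):
        for j in range(i + 1, p):
            if a[i, j] > 0:
                g.add_edge(i, j, distance=1.0 / a[i, j])
    node_order = list(range(p))
    best_membership = _components_membership(g, node_order)
    best_q = modularity(a, best_membership)
    n_comp = int(best_membership.max()) + 1
    work = g.copy()
    while work.number_of_edges() > 0:
        bc = nx.edge_betweenness_centrality(work, weight="distance")
        best_edge = None
        best_val = -np.inf
        for (u, v), val in bc.items():
            key = tuple(sorted((u, v)))
            if val > best_val + 1e-12 or (
                abs(val - best_val) <= 1e-12
                and (best_edge is None or key < best_edge)
            ):
                best_val = val
                best_edge = key
        work.remove_edge(*best_edge)
        membership = _components_membership(work, node_order)
        k = int(membership.max()) + 1
        if k > n_comp:  # partition only changes when a component splits
            n_comp = k
            q = modularity(a, membership)
            if q > best_q + 1e-12:
                best_q = q
                best_membership = membership
    membership = _canonical_membership(best_membership)
    if exhaustive_check:
        opt_q, _ = exhaustive_best_partition(a)
        params["exhaustive_gap"] = opt_q - best_q
    return Partition(_node_names(net, p), membership, best_q, "edge_betweenness", params)


def _set_partitions(p: int):
    """All partitions of range(p) as restricted-growth membership arrays."""
    membership = np.zeros(p, dtype=np.int64)

    def rec(i: int, n_used: int):
        if i == p:
            yield membership.copy()
            return
        for c in range(n_used + 1):
            membership[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(1, 1)


def exhaustive_best_partition(
    net: IsingNetwork | np.ndarray, max_p: int = 10
) -> tuple[float, np.ndarray]:
    """Exhaustive modularity maximization over all set partitions.

    Oracle for small graphs (Bell(10) = 115975 partitions); refuses
    beyond ``max_p``.
    """
    a = _abs_weights(net)
    p = a.shape[0]
    if p > max_p:
        raise ValueError(f"exhaustive search limited to p <= {max_p} nodes")
    if a.sum() == 0:
        return 0.0, np.zeros(p, dtype=np.int64)
    two_m = a.sum()
    k = a.sum(axis=1)
    b = a - np.outer(k, k) / two_m
    best_q, best_m = -np.inf, None
    for membership in _set_partitions(p):
        same = membership[:, None] == membership[None, :]
        q = b[same].sum() / two_m
        if q > best_q + 1e-15:
            best_q, best_m = q, membership
    return float(best_q), best_m


def community_report(
    partitions: dict[str, Partition], threshold: float = 0.30
) -> dict[str, pd.DataFrame]:
    """Cross-group community summary.

    Returns ``summary`` (per group: communities, Q, clear-structure flag),
    ``agreement`` (pairwise adjusted Rand indices) and ``membership`` (per
    node, community id in each group — the tabular analogue of coloring
    nodes across network plots).
    """
    if not partitions:
        raise ValueError("need at least one partition")
    names = list(partitions)
    summary = pd.DataFrame(
        {
            "n_communities": [partitions[g].n_communities for g in names],
            "modularity_q": [partitions[g].modularity_q for g in names],
            "clear_structure": [partitions[g].modularity_q > threshold for g in names],
        },
        index=names,
    )
    agreement = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, ga in enumerate(names):
        for j, gb in enumerate(names):
            if i < j:
                ari = adjusted_rand_score(
                    partitions[ga].membership, partitions[gb].membership
                )
                agreement.iloc[i, j] = agreement.iloc[j, i] = ari
    membership = pd.DataFrame(
        {g: pd.Series(partitions[g].as_dict()) for g in names}
    )
    return {"summary": summary, "agreement": agreement, "membership": membership}
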