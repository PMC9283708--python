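"""Contact networks of cell configurations and their structural measures.

A tumor's contact network has one node per cell and an undirected link
between two cells whenever their center distance is at most one cell
diameter (the contact threshold).  Cells with no contact at all are *not*
part of the network — they are counted separately — so every node has
degree at least one and, for hard discs in the plane, at most six (the 2-D
kissing number; degree-6 nodes are the "stiff" nodes whose fraction tracks
solid-like order).

The measures implemented here are the standard ones of network science,
computed from scratch so they can be cross-checked against independent
oracles: the degree distribution ``P_k``, average degree ``<k> = 2L/N``,
average nearest-neighbor degree ``K_nn``, transitivity (global clustering,
triangles over connected triples), per-node and mean local clustering, and
the connected components found by breadth-first search.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ContactNetwork",
    "NetworkSummary",
    "build_contact_network",
    "degree_distribution",
    "average_degree",
    "nearest_neighbor_degree",
    "transitivity",
    "clustering",
    "connected_components",
    "summarize",
]

# Absolute fuzz on the inclusive distance threshold so that fixtures built
# at spacing exactly 1 link despite floating-point roundoff.
_EPS = 1e-9


class EmptyNetworkError(ValueError):
    """Raised when a measure is requested on a network with no nodes."""


@dataclass
class ContactNetwork:
    """Undirected contact graph on the non-isolated cells.

    ``neighbors`` maps each retained cell id to a sorted tuple of neighbor
    ids; ``node_ids`` is sorted.  Isolated cells are excluded from the node
    set but counted in ``n_isolated`` (and listed in ``isolated_ids``).
    """

    node_ids: np.ndarray
    neighbors: dict
    isolated_ids: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_isolated(self) -> int:
        return len(self.isolated_ids)

    @property
    def n_links(self) -> int:
        return sum(len(v) for v in self.neighbors.values()) // 2

    @property
    def degrees(self) -> np.ndarray:
        """Degree of each node, aligned with ``node_ids``."""
        return np.array([len(self.neighbors[i]) for i in self.node_ids], dtype=np.int64)

    def edges(self):
        """Yield each undirected edge once as (i, j) with i < j."""
        for i in self.node_ids:
            for j in self.neighbors[i]:
                if i < j:
                    yield (int(i), int(j))


@dataclass
class NetworkSummary:
    """All scalar and distributional measures of one contact network."""

    n_nodes: int
    n_links: int
    n_isolated: int
    degree_dist: dict            # {k: P_k}
    mean_degree: float
    knn: float
    transitivity: float
    mean_clustering: float
    n_components: int
    component_sizes: list
    largest_component: int
    components_per_node: float   # rho_c = N_c / N

    def measures(self) -> dict:
        """Flat scalar view used by sweep aggregation and JSON export."""
        return {
            "n_nodes": float(self.n_nodes),
            "n_links": float(self.n_links),
            "n_isolated": float(self.n_isolated),
            "total_cells": float(self.n_nodes + self.n_isolated),
            "P_2": self.degree_dist.get(2, 0.0),
            "P_6": self.degree_dist.get(6, 0.0),
            "mean_degree": self.mean_degree,
            "knn": self.knn,
            "transitivity": self.transitivity,
            "mean_clustering": self.mean_clustering,
            "n_components": float(self.n_components),
            "s_max": float(self.largest_component),
            "rho_c": self.components_per_node,
        }


def build_contact_network(config, threshold: float = 1.0) -> ContactNetwork:
    """Build the contact graph: link two cells iff center distance <= threshold.

    Accepts a :class:`~tumornet.dynamics.CellConfiguration` or a raw (N, 2)
    position array (ids then default to 0..N-1).
    """
    pos = np.asarray(getattr(config, "positions", config), dtype=float).reshape(-1, 2)
    ids = np.asarray(getattr(config, "ids", np.arange(len(pos))), dtype=np.int64)
    n = len(pos)
    adj: dict[int, set] = {int(i): set() for i in ids}
    if n > 1:
        pairs = cKDTree(pos).query_pairs(threshold + _EPS, output_type="ndarray")
        for a, b in pairs:
            ia, ib = int(ids[a]), int(ids[b])
            adj[ia].add(ib)
            adj[ib].add(ia)
    node_ids = np.array(sorted(i for i, s in adj.items() if s), dtype=np.int64)
    isolated = np.array(sorted(i for i, s in adj.items() if not s), dtype=np.int64)
    neighbors = {int(i): tuple(sorted(adj[int(i)])) for i in node_ids}
    return ContactNetwork(node_ids=node_ids, neighbors=neighbors, isolated_ids=isolated)


def _require_nodes(net: ContactNetwork) -> None:
    if net.n_nodes == 0:
        raise EmptyNetworkError("measure undefined on an empty contact network")


def degree_distribution(net: ContactNetwork) -> dict:
    """Degree distribution ``P_k`` = fraction of nodes with degree k.

    Support is within [1, observed max]; values sum to one.
    """
    _require_nodes(net)
    degs = net.degrees
    ks, counts = np.unique(degs, return_counts=True)
    return {int(k): c / net.n_nodes for k, c in zip(ks, counts)}


def average_degree(net: ContactNetwork) -> float:
    """Mean degree ``<k> = (1/N) sum k_i = 2L/N``."""
    _require_nodes(net)
    return float(net.degrees.mean())


def nearest_neighbor_degree(net: ContactNetwork) -> float:
    """Average nearest-neighbor degree ``K_nn``.

    ``(1/N) sum_i (1/k_i) sum_{j in N_i} k_j`` — the network-wide mean of
    each node's mean neighbor degree; a degree-correlation (homogeneity)
    measure.
    """
    _require_nodes(net)
    total = 0.0
    for i in net.node_ids:
        nbrs = net.neighbors[int(i)]
        total += sum(len(net.neighbors[j]) for j in nbrs) / len(nbrs)
    return total / net.n_nodes


def _links_among_neighbors(net: ContactNetwork, i: int) -> int:
    nbrs = net.neighbors[i]
    nbr_set = set(nbrs)
    cnt = 0
    for j in nbrs:
        cnt += len(nbr_set.intersection(net.neighbors[j]))
    return cnt // 2


def transitivity(net: ContactNetwork) -> float:
    """Global clustering coefficient: 3 * triangles / connected triples.

    Equals ``trace(A^3) / sum_i k_i (k_i - 1)`` on the adjacency matrix;
    returns 0 when the network has no connected triples.
    """
    _require_nodes(net)
    triangles3 = 0  # sum over nodes of links among neighbors = 3 * n_triangles
    triples2 = 0    # sum over nodes of k (k - 1)
    for i in net.node_ids:
        i = int(i)
        k = len(net.neighbors[i])
        triples2 += k * (k - 1)
        triangles3 += _links_among_neighbors(net, i)
    if triples2 == 0:
        return 0.0
    return 2.0 * triangles3 / triples2


def clustering(net: ContactNetwork):
    """Per-node clustering ``C_i = 2 L_i / (k_i (k_i - 1))`` and its mean.

    ``L_i`` is the number of links among node i's neighbors; ``C_i`` is
    defined as 0 for degree-1 nodes (standard convention for the 0/0 case).

    Returns
    -------
    (dict, float)
        ``{node_id: C_i}`` and the network mean ``<C>``.
    """
    _require_nodes(net)
    ci = {}
    for i in net.node_ids:
        i = int(i)
        k = len(net.neighbors[i])
        if k < 2:
            ci[i] = 0.0
        else:
            ci[i] = 2.0 * _links_among_neighbors(net, i) / (k * (k - 1))
    return ci, float(np.mean(list(ci.values())))


def connected_components(net: ContactNetwork):
    """Connected components by breadth-first search.

    Returns
    -------
    (dict, list)
        ``{node_id: component_label}`` with labels 0..N_c-1 in order of
        discovery (lowest node id first), and the list of component sizes
        in label order.
    """
    labels: dict[int, int] = {}
    sizes: list[int] = []
    for start in net.node_ids:
        start = int(start)
        if start in labels:
            continue
        label = len(sizes)
        queue = deque([start])
        labels[start] = label
        count = 0
        while queue:
            u = queue.popleft()
            count += 1
            for v in net.neighbors[u]:
                if v not in labels:
                    labels[v] = label
                    queue.append(v)
        sizes.append(count)
    return labels, sizes


def summarize(net: ContactNetwork) -> NetworkSummary:
    """Compute every measure of a (non-empty) network in one record."""
    _require_nodes(net)
    _, sizes = connected_components(net)
    _, mean_c = clustering(net)
    summary = NetworkSummary(
        n_nodes=net.n_nodes,
        n_links=net.n_links,
        n_isolated=net.n_isolated,
        degree_dist=degree_distribution(net),
        mean_degree=average_degree(net),
        knn=nearest_neighbor_degree(net),
        transitivity=transitivity(net),
        mean_clustering=mean_c,
        n_components=len(sizes),
        component_sizes=sorted(sizes, reverse=True),
        largest_component=max(sizes),
        components_per_node=len(sizes) / net.n_nodes,
    )
    # internal consistency
    assert abs(sum(summary.degree_dist.values()) - 1.0) < 1e-9
    assert sum(sizes) == summary.n_nodes
    assert abs(summary.mean_degree - 2.0 * summary.n_links / summary.n_nodes) < 1e-9
    return summary
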