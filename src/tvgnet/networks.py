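"""Network construction and developmental analysis of a graph series.

Each fitted precision matrix becomes an undirected network whose edges are
the off-diagonal entries above tolerance; genes without any connection are
dropped, so node counts mean connected nodes. The series is characterized
by global properties (nodes, edges, density, diameter, exclusive edges),
pairwise similarity via the neighbor-overlap index CNSI, average-linkage
hierarchical clustering of the networks into developmental stages, and
degree-based hub identification.

CNSI between networks A and B sums, over nodes of the union universe, the
Jaccard overlap of the node's first-neighbor sets in A and B (an absent node
has an empty neighbor set; 0/0 counts as 0) and normalizes by the size of
the union, so the score lies in [0, 1] with 1 for identical networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkSeries",
    "network_from_precision",
    "global_properties",
    "exclusive_edges",
    "degree_centrality",
    "identify_hubs",
    "cnsi",
    "similarity_matrix",
    "cluster_networks",
]


@dataclass
class NetworkSeries:
    """Ordered, labelled networks over one gene universe."""

    labels: list[str]
    graphs: list[nx.Graph]
    universe: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.graphs):
            raise ValueError("one label per network required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    def __len__(self) -> int:
        return len(self.graphs)


def network_from_precision(
    omega: np.ndarray,
    gene_ids: Sequence[str],
    tol: float = 1e-6,
) -> nx.Graph:
    """Undirected network of the precision support; isolated genes dropped."""
    omega = np.asarray(omega)
    p = omega.shape[0]
    if len(gene_ids) != p:
        raise ValueError("gene_ids length must match matrix dimension")
    g = nx.Graph()
    iu = np.triu_indices(p, k=1)
    mask = np.abs(omega[iu]) > tol
    for u, v in zip(iu[0][mask], iu[1][mask]):
        g.add_edge(gene_ids[u], gene_ids[v], weight=float(omega[u, v]))
    return g


def global_properties(net: nx.Graph) -> dict[str, float]:
    """Connected-node count, edge count, density and diameter.

    Density is ``2|E| / (|V|(|V|-1))`` (0 when |V| < 2). The diameter is the
    maximum shortest-path length over connected node pairs, i.e. the largest
    component diameter; an edgeless network has diameter 0.
    """
    n = net.number_of_nodes()
    e = net.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n >= 2 else 0.0
    diameter = 0
    for comp in nx.connected_components(net):
        if len(comp) >= 2:
            diameter = max(diameter, nx.diameter(net.subgraph(comp)))
    return {"n_nodes": n, "n_edges": e, "density": density, "diameter": diameter}


def _edge_set(net: nx.Graph) -> frozenset[tuple[str, str]]:
    return frozenset(tuple(sorted(e)) for e in net.edges())


def exclusive_edges(series: NetworkSeries) -> list[frozenset[tuple[str, str]]]:
    """Edges of each network that appear in no other network of the series."""
    if len(series) < 2:
        raise ValueError("need at least two networks")
    sets = [_edge_set(g) for g in series.graphs]
    out = []
    for i, s in enumerate(sets):
        others = frozenset().union(*(sets[j] for j in range(len(sets)) if j != i))
        out.append(frozenset(s - others))
    return out


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Per-node degree C_d(i) = deg(i); degrees sum to 2|E|."""
    return dict(net.degree())


def identify_hubs(net: nx.Graph, k: int = 3) -> list[str]:
    """The ``k`` highest-degree nodes, ties broken lexicographically by id."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if net.number_of_nodes() == 0:
        warnings.warn("empty network: no hubs to report", stacklevel=2)
        return []
    deg = degree_centrality(net)
    ranked = sorted(deg, key=lambda v: (-deg[v], str(v)))
    if k > len(ranked):
        warnings.warn(
            f"requested {k} hubs but network has only {len(ranked)} nodes",
            stacklevel=2,
        )
    return ranked[:k]


def cnsi(a: nx.Graph, b: nx.Graph) -> float:
    """Neighbor-overlap similarity between two networks, in [0, 1].

    Per node of V(A) ∪ V(B), the Jaccard index of its first-neighbor sets in
    the two networks (empty set for an absent node; 0/0 := 0); the sum is
    normalized by |V(A) ∪ V(B)|.
    """
    nodes = set(a.nodes()) | set(b.nodes())
    if not nodes:
        raise ValueError("similarity of two empty networks is undefined")
    total = 0.0
    for v in nodes:
        na = set(a.neighbors(v)) if v in a else set()
        nb = set(b.neighbors(v)) if v in b else set()
        union = na | nb
        if union:
            total += len(na & nb) / len(union)
    return total / len(nodes)


def similarity_matrix(series: NetworkSeries) -> np.ndarray:
    """Pairwise CNSI; symmetric with unit diagonal."""
    if len(series) < 2:
        raise ValueError("need at least two networks")
    n = len(series)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sim[i, j] = sim[j, i] = cnsi(series.graphs[i], series.graphs[j])
    return sim


def cluster_networks(
    sim: np.ndarray, n_stages: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering of networks on dissimilarity 1 - CNSI.

    Returns the scipy linkage matrix (the dendrogram) and flat stage labels
    (0-based) from cutting the tree into ``n_stages`` groups.
    """
    sim = np.asarray(sim, dtype=float)
    n = sim.shape[0]
    if not 1 <= n_stages <= n:
        raise ValueError(f"n_stages must be in [1, {n}]")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(0.5 * (dist + dist.T), 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=n_stages, criterion="maxclust") - 1
    return z, labels
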