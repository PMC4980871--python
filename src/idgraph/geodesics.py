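"""k-nearest-neighbor graphs and shortest-path (graph geodesic) distances.

The neighbor graph is the symmetric union: edge (i, j) exists if j is among
the k nearest neighbors of i *or* vice versa, weighted by the input-space
distance.  Shortest paths on this graph approximate manifold geodesics; the
approximation is exact for graph neighbors and an upper bound on the
input-space distance for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .metrics import DistanceSet
from .shapes import PointCloud

__all__ = [
    "NeighborGraph",
    "build_knn_graph",
    "knn_graph_from_points",
    "restrict_to_lcc",
    "graph_geodesics",
]


@dataclass
class NeighborGraph:
    """Weighted undirected union k-NN graph with connectivity bookkeeping."""

    adjacency: csr_matrix
    k: int
    component_labels: np.ndarray = field(init=False)
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_components, self.component_labels = connected_components(
            self.adjacency, directed=False)

    @property
    def n_points(self) -> int:
        return self.adjacency.shape[0]

    @property
    def lcc_size(self) -> int:
        return int(np.bincount(self.component_labels).max())

    @property
    def is_connected(self) -> bool:
        return self.n_components == 1

    def lcc_indices(self) -> np.ndarray:
        """Indices of the largest connected component.

        Ties between equally sized components are broken toward the
        component containing the lowest point index.
        """
        sizes = np.bincount(self.component_labels)
        best = np.flatnonzero(sizes == sizes.max())
        if len(best) > 1:
            first_member = [np.flatnonzero(self.component_labels == c)[0]
                            for c in best]
            best = [best[int(np.argmin(first_member))]]
        return np.flatnonzero(self.component_labels == best[0])


def build_knn_graph(dist: DistanceSet, k: int) -> NeighborGraph:
    """Union k-NN graph from a complete condensed distance set.

    Neighbors are the k smallest distances excluding self; equidistant
    candidates are broken by point index (stable sort), and duplicate
    points (distance 0) count individually.  Materializes the square matrix,
    so intended for N up to ~10^4.
    """
    n = dist.n_points
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    if not dist.is_complete:
        raise ValueError("graph construction needs a complete distance set")
    square = dist.to_square()
    np.fill_diagonal(square, np.inf)
    order = np.argsort(square, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    w = square[rows, cols]
    adj = csr_matrix((w, (rows, cols)), shape=(n, n))
    adj = adj.maximum(adj.T)
    return NeighborGraph(adj, k)


def knn_graph_from_points(cloud: PointCloud, k: int) -> NeighborGraph:
    """Union k-NN graph straight from coordinates (Euclidean metric).

    Avoids the N x N matrix of :func:`build_knn_graph` by using a spatial
    index; preferred for coordinate input.
    """
    from sklearn.neighbors import kneighbors_graph

    n = cloud.n_points
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    adj = kneighbors_graph(cloud.coords, k, mode="distance")
    adj = adj.maximum(adj.T)
    return NeighborGraph(csr_matrix(adj), k)


def restrict_to_lcc(graph: NeighborGraph, dist: DistanceSet | None = None):
    """Restrict a graph (and optionally its distance set) to the largest
    connected component.

    Returns ``(graph, dist, index_map)`` where ``index_map`` holds the
    original indices of the retained nodes.  A connected graph is returned
    unchanged.
    """
    keep = graph.lcc_indices()
    if len(keep) == graph.n_points:
        return graph, dist, np.arange(graph.n_points)
    sub = NeighborGraph(graph.adjacency[np.ix_(keep, keep)], graph.k)
    new_dist = None
    if dist is not None:
        square = dist.to_square()[np.ix_(keep, keep)]
        from scipy.spatial.distance import squareform

        new_dist = DistanceSet(squareform(square, checks=False), len(keep),
                               dist.metric_tag, meta=dict(dist.meta))
    return sub, new_dist, keep


def graph_geodesics(graph: NeighborGraph, sources: np.ndarray | None = None,
                    ) -> DistanceSet:
    """Shortest-path distances on the neighbor graph.

    With ``sources=None`` all N(N-1)/2 pairs are returned condensed;
    otherwise only pairs with at least one endpoint in ``sources`` are kept
    (each distinct pair once).  Requires a connected graph -- restrict to
    the largest component first (:func:`restrict_to_lcc`) otherwise.
    """
    if not graph.is_connected:
        raise ValueError(
            f"graph has {graph.n_components} components "
            f"(largest: {graph.lcc_size}/{graph.n_points} nodes); "
            "restrict to the largest connected component first")
    n = graph.n_points
    if sources is None:
        full = dijkstra(graph.adjacency, directed=False)
        iu = np.triu_indices(n, 1)
        return DistanceSet(full[iu], n, "graph", meta={"k": graph.k})
    sources = np.unique(np.asarray(sources, dtype=int))
    if np.any(sources < 0) or np.any(sources >= n):
        raise ValueError("source indices out of range")
    rows = dijkstra(graph.adjacency, directed=False, indices=sources)
    is_source = np.zeros(n, dtype=bool)
    is_source[sources] = True
    vals = []
    for row_idx, s in enumerate(sources):
        # keep (s, j) once: all non-sources, plus sources with larger index
        mask = ~is_source
        mask = mask.copy()
        mask[sources[sources > s]] = True
        mask[s] = False
        vals.append(rows[row_idx, mask])
    return DistanceSet(np.concatenate(vals), n, "graph",
                       is_complete=False,
                       meta={"k": graph.k, "n_sources": len(sources)})
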