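"""Spatial k-nearest-neighbor graphs over segmented cells.

The graph is the union of each cell's k nearest neighbors (so adjacency is
symmetric and interior cells have degree >= k), with Euclidean edge lengths
in μm. Distance ties are broken toward the lowest cell_id, which makes graph
construction deterministic; CellMap stores cells sorted by cell_id so a
stable argsort realizes exactly that rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .data import CellMap

__all__ = ["SpatialGraph", "build_knn_graph", "knn_indices"]

# Coincident cells would produce zero-length edges that sparse storage drops;
# clamp to a length far below any physical cell spacing instead.
_MIN_EDGE = 1e-12


def knn_indices(coords: np.ndarray, k: int) -> np.ndarray:
    """Indices of each point's k nearest neighbors (self excluded).

    Rows follow the input order; ties resolve to the lower row index via a
    stable sort. ``k`` truncates to n-1.
    """
    n = len(coords)
    kk = min(k, n - 1)
    d = cdist(coords, coords)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, 1 : kk + 1]


@dataclass
class SpatialGraph:
    """Undirected kNN-union graph with Euclidean edge weights (μm)."""

    cell_ids: np.ndarray
    coords: np.ndarray
    k: int
    adjacency: sp.csr_matrix  # symmetric, weights = edge lengths
    _neighbors: list[np.ndarray] = field(default_factory=list, repr=False)
    _component_labels: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    def neighbors(self, i: int) -> np.ndarray:
        """Neighbor node indices of node i (sorted ascending)."""
        if not self._neighbors:
            A = self.adjacency
            self._neighbors = [A.indices[A.indptr[j] : A.indptr[j + 1]] for j in range(self.n_nodes)]
        return self._neighbors[i]

    def edge_weight(self, i: int, j: int) -> float:
        return float(self.adjacency[i, j])

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edge list (both orientations) as (source, target) arrays."""
        coo = self.adjacency.tocoo()
        return coo.row, coo.col

    def component_labels(self) -> np.ndarray:
        if self._component_labels is None:
            _, labels = connected_components(self.adjacency, directed=False)
            self._component_labels = labels
        return self._component_labels

    def to_networkx(self):
        """Export as a networkx Graph with 'length' edge attributes."""
        import networkx as nx

        g = nx.Graph()
        for i, cid in enumerate(self.cell_ids):
            g.add_node(i, cell_id=cid, x=self.coords[i, 0], y=self.coords[i, 1])
        coo = sp.triu(self.adjacency).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            g.add_edge(int(i), int(j), length=float(w))
        return g


def build_knn_graph(cellmap: CellMap, k: int) -> SpatialGraph:
    """Build the symmetric k-nearest-neighbor union graph of one ROI.

    Each cell is connected to its k nearest neighbors by Euclidean distance;
    the union of directed neighborhoods gives an undirected graph, so cells
    that are someone's near neighbor can exceed degree k. ``k`` silently
    truncates when the ROI has fewer than k+1 cells.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    coords = cellmap.coords
    n = len(coords)
    if n < 2:
        raise ValueError("kNN graph needs at least 2 cells")
    neigh = knn_indices(coords, k)
    kk = neigh.shape[1]
    rows = np.repeat(np.arange(n), kk)
    cols = neigh.ravel()
    dist = np.linalg.norm(coords[rows] - coords[cols], axis=1)
    data = np.maximum(dist, _MIN_EDGE)
    A = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    A = A.maximum(A.T)  # union symmetrization
    A.sort_indices()
    return SpatialGraph(cell_ids=cellmap.cell_ids, coords=coords, k=k, adjacency=A)
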