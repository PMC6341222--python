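"""Distance-thresholded Delaunay cell graphs.

The cell graph approximates which cells are in physical contact: vertices
are nucleus centroids, and two vertices are connected iff the pair is an
edge of the Delaunay triangulation of all centroids AND their Euclidean
distance is strictly below a cutoff (30 µm by default, on the scale of two
nuclear radii plus cytoplasm). The strict inequality means an edge of
length exactly equal to the cutoff is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Hashable, Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

DEFAULT_CUTOFF_UM = 30.0


@dataclass
class CellGraph:
    """Undirected neighbourhood graph over nucleus centroids.

    ``vertex_ids`` keeps the input order; ``edges`` holds index pairs
    ``(i, j)`` with ``i < j`` into that order. Use :meth:`neighbors` for
    id-level queries.
    """

    vertex_ids: list[Hashable]
    positions: np.ndarray  # (n, 3) µm
    edges: set[tuple[int, int]]
    cutoff: float = DEFAULT_CUTOFF_UM
    _index: dict[Hashable, int] = field(init=False, repr=False)
    _adj: dict[int, set[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.vertex_ids)}
        self._adj = {i: set() for i in range(len(self.vertex_ids))}
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop at vertex {self.vertex_ids[i]}")
            self._adj[i].add(j)
            self._adj[j].add(i)

    def __len__(self) -> int:
        return len(self.vertex_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def neighbors(self, nucleus_id: Hashable) -> set[Hashable]:
        """Ids sharing an edge with ``nucleus_id`` (empty for isolated cells)."""
        if nucleus_id not in self._index:
            raise KeyError(f"unknown nucleus id {nucleus_id!r}")
        return {self.vertex_ids[j] for j in self._adj[self._index[nucleus_id]]}

    def neighbor_indices(self, i: int) -> set[int]:
        return self._adj[i]

    def degree(self, nucleus_id: Hashable) -> int:
        return len(self._adj[self._index[nucleus_id]])

    def edge_ids(self) -> list[tuple[Hashable, Hashable]]:
        return [(self.vertex_ids[i], self.vertex_ids[j]) for i, j in sorted(self.edges)]

    def edge_lengths(self) -> np.ndarray:
        if not self.edges:
            return np.empty(0)
        idx = np.array(sorted(self.edges))
        return np.linalg.norm(self.positions[idx[:, 0]] - self.positions[idx[:, 1]], axis=1)

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoints as two index arrays (deterministic order)."""
        if not self.edges:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        idx = np.array(sorted(self.edges))
        return idx[:, 0], idx[:, 1]


def _check_positions(positions: np.ndarray, ids: Sequence[Hashable]) -> None:
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite coordinate in positions")
    # duplicate centroids make zero-length edges undefined and indicate
    # upstream segmentation faults; name the offending pair
    order = np.lexsort(positions.T)
    same = np.all(positions[order[1:]] == positions[order[:-1]], axis=1)
    if np.any(same):
        k = int(np.argmax(same))
        a, b = order[k], order[k + 1]
        raise ValueError(f"duplicate centroids: nuclei {ids[a]!r} and {ids[b]!r}")


def _delaunay_edge_indices(positions: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edges with degeneracy fallbacks.

    <4 points (or rank-deficient sets where a 3D triangulation is undefined):
    coplanar sets are triangulated in their best-fit plane, collinear sets
    connect consecutive points along the line, and tiny sets connect all
    pairs. The length cutoff is applied by the caller.
    """
    n = len(positions)
    if n <= 2:
        return {(i, j) for i, j in combinations(range(n), 2)}

    centered = positions - positions.mean(axis=0)
    # numerical rank decides the embedding dimension
    svals = np.linalg.svd(centered, compute_uv=False)
    scale = svals[0] if svals[0] > 0 else 1.0
    rank = int(np.sum(svals > 1e-9 * scale))

    if rank <= 1:
        # collinear: neighbours along the line
        t = centered @ np.linalg.svd(centered, full_matrices=False)[2][0]
        order = np.argsort(t, kind="stable")
        return {tuple(sorted((int(order[k]), int(order[k + 1])))) for k in range(n - 1)}

    if rank == 2 or n < 4:
        if n == 3:
            return {(0, 1), (0, 2), (1, 2)}
        vt = np.linalg.svd(centered, full_matrices=False)[2]
        planar = centered @ vt[:2].T
        tri = Delaunay(planar)
    else:
        try:
            tri = Delaunay(positions)
        except QhullError:
            # nearly coplanar sets that pass the rank test but break qhull
            vt = np.linalg.svd(centered, full_matrices=False)[2]
            tri = Delaunay(centered @ vt[:2].T)

    edges: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for a, b in combinations(simplex, 2):
            edges.add((int(min(a, b)), int(max(a, b))))
    return edges


def build_cell_graph(
    positions: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF_UM,
    ids: Sequence[Hashable] | None = None,
) -> CellGraph:
    """Build the neighbourhood graph for one specimen.

    Parameters
    ----------
    positions:
        (n, 3) centroid coordinates in µm (an (n, 2) array is accepted and
        zero-padded — useful for planar toy examples).
    cutoff:
        Edge length threshold in µm; edges of length >= cutoff are removed
        (strictly-less-than test).
    ids:
        Optional per-vertex nucleus ids; defaults to integer indices.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        positions = positions.reshape(1, -1)
    if positions.shape[1] == 2:
        positions = np.hstack([positions, np.zeros((len(positions), 1))])
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError("positions must be an (n, 3) array")
    if len(positions) < 1:
        raise ValueError("need at least one point")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if ids is None:
        ids = list(range(len(positions)))
    else:
        ids = list(ids)
        if len(ids) != len(positions):
            raise ValueError("ids and positions length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate nucleus ids")
    _check_positions(positions, ids)

    edges = set()
    for i, j in _delaunay_edge_indices(positions):
        if np.linalg.norm(positions[i] - positions[j]) < cutoff:
            edges.add((i, j))
    return CellGraph(vertex_ids=ids, positions=positions, edges=edges, cutoff=cutoff)


def neighbors(graph: CellGraph, nucleus_id: Hashable) -> set[Hashable]:
    """Functional alias for :meth:`CellGraph.neighbors`."""
    return graph.neighbors(nucleus_id)


def graph_to_edge_table(graph: CellGraph, specimen_id: str = ""):
    """Edge list as a DataFrame (specimen_id, id_a, id_b, length_um)."""
    import pandas as pd

    ia, ib = graph.edge_arrays()
    lengths = np.linalg.norm(graph.positions[ia] - graph.positions[ib], axis=1) if len(ia) else np.empty(0)
    return pd.DataFrame(
        {
            "specimen_id": [specimen_id] * len(ia),
            "id_a": [graph.vertex_ids[i] for i in ia],
            "id_b": [graph.vertex_ids[j] for j in ib],
            "length_um": lengths,
        }
    )
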