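"""Delaunay neighbour networks and Euclidean minimum spanning trees.

The Delaunay triangulation (dual of the Voronoi diagram) links each stoma to
its natural neighbours; in a homogeneous planar pattern the mean vertex
degree tends to six. The Euclidean MST — the spanning tree minimising total
edge length — is always a subgraph of the Delaunay triangulation, so the
EMST is extracted by running a minimum-spanning-tree pass over Delaunay
edges only (O(n log n)) instead of the complete graph; for degenerate
geometry (n < 3, collinear points) the complete graph is used directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist

from stomanet.patterns import PointPattern


class DegenerateGeometryError(ValueError):
    """Triangulation impossible: fewer than 3 points or all collinear."""


@dataclass(frozen=True)
class SpatialGraph:
    """Undirected geometric graph over a point pattern.

    ``edges`` is an (m, 2) integer array with i < j per row; ``lengths``
    holds the matching Euclidean distances in mm.
    """

    pattern: PointPattern
    edges: np.ndarray
    lengths: np.ndarray
    kind: Literal["delaunay", "mst"]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.pattern.n, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg


@dataclass(frozen=True)
class MSTSummary:
    """Total length, edge count and edge-length moments of one sample's MST.

    All lengths in mm. ``mean_edge`` and ``sd_edge`` are NaN for trees with
    no edges (n <= 1).
    """

    total_length: float
    n_edges: int
    mean_edge: float
    sd_edge: float


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Unique undirected Delaunay edges as an (m, 2) array with i < j."""
    tri = Delaunay(points)
    s = tri.simplices
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e.sort(axis=1)
    # encode as 1-D keys for a fast unique (np.unique over rows is slow)
    n = len(points)
    keys = e[:, 0].astype(np.int64) * n + e[:, 1]
    keys = np.unique(keys)
    return np.column_stack([keys // n, keys % n])


def _complete_edges(points: np.ndarray) -> np.ndarray:
    n = len(points)
    iu = np.triu_indices(n, k=1)
    return np.column_stack(iu)


def _edge_lengths(points: np.ndarray, edges: np.ndarray) -> np.ndarray:
    diff = points[edges[:, 0]] - points[edges[:, 1]]
    return np.hypot(diff[:, 0], diff[:, 1])


def build_delaunay(pattern: PointPattern) -> SpatialGraph:
    """Delaunay triangulation of the pattern as an edge graph.

    Raises
    ------
    DegenerateGeometryError
        If n < 3 or the points are collinear; callers that only need the
        MST should use :func:`compute_emst`, which falls back to the
        complete graph.
    """
    pts = pattern.points
    if pattern.n < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {pattern.n}")
    try:
        edges = _delaunay_edges(pts)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate geometry: {exc}") from exc
    return SpatialGraph(pattern, edges, _edge_lengths(pts, edges), "delaunay")


def _mst_from_edges(n: int, edges: np.ndarray, lengths: np.ndarray):
    graph = coo_matrix((lengths, (edges[:, 0], edges[:, 1])), shape=(n, n))
    tree = minimum_spanning_tree(graph).tocoo()
    te = np.column_stack([np.minimum(tree.row, tree.col), np.maximum(tree.row, tree.col)])
    tl = tree.data
    # deterministic presentation order: (length, i, j)
    order = np.lexsort((te[:, 1], te[:, 0], tl))
    return te[order], tl[order]


def compute_emst(pattern: PointPattern) -> SpatialGraph:
    """Euclidean minimum spanning tree of the pattern.

    n <= 1 yields an empty edge set, n == 2 the single connecting edge.
    Otherwise the MST is extracted from the Delaunay edges, falling back to
    the complete graph on degenerate geometry. Total weight is the global
    minimum over all spanning trees; edge identity under exact length ties
    follows the deterministic scan order of the extraction, so repeated runs
    on the same input give byte-identical edge lists.
    """
    pts = pattern.points
    n = pattern.n
    if n <= 1:
        empty = np.empty((0, 2), dtype=int)
        return SpatialGraph(pattern, empty, np.empty(0), "mst")
    if n == 2:
        edges = np.array([[0, 1]])
        return SpatialGraph(pattern, edges, _edge_lengths(pts, edges), "mst")
    try:
        edges = _delaunay_edges(pts)
    except QhullError:
        edges = _complete_edges(pts)
    te, tl = _mst_from_edges(n, edges, _edge_lengths(pts, edges))
    return SpatialGraph(pattern, te, tl, "mst")


def mst_total_length(points: np.ndarray) -> float:
    """Total EMST length of a raw (n, 2) coordinate array.

    Fast path used inside Monte-Carlo envelope loops; skips pattern
    validation and graph-object construction.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= 1:
        return 0.0
    if n == 2:
        return float(np.hypot(*(pts[0] - pts[1])))
    try:
        edges = _delaunay_edges(pts)
    except QhullError:
        edges = _complete_edges(pts)
    graph = coo_matrix(
        (_edge_lengths(pts, edges), (edges[:, 0], edges[:, 1])), shape=(n, n)
    )
    return float(minimum_spanning_tree(graph).sum())


def mst_summary(mst: SpatialGraph) -> MSTSummary:
    """Summary statistics (mm) of an MST graph."""
    if mst.kind != "mst":
        raise ValueError(f"expected an MST graph, got kind={mst.kind!r}")
    m = mst.n_edges
    if m == 0:
        return MSTSummary(0.0, 0, float("nan"), float("nan"))
    lengths = mst.lengths
    return MSTSummary(
        total_length=float(lengths.sum()),
        n_edges=m,
        mean_edge=float(lengths.mean()),
        sd_edge=float(lengths.std(ddof=0)),
    )


def brute_force_mst_length(points: np.ndarray) -> float:
    """Reference EMST length via the complete graph (O(n^2) edges).

    Independent cross-check for the Delaunay-restricted extraction; intended
    for small n only.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= 1:
        return 0.0
    edges = _complete_edges(pts)
    graph = coo_matrix((pdist(pts), (edges[:, 0], edges[:, 1])), shape=(n, n))
    return float(minimum_spanning_tree(graph).sum())
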