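"""Synthetic grayordinate geometry.

The analysis domain is a stand-in for the combined cortical-surface /
subcortical "grayordinate" space: two hemispheres of vertices sampled on a
unit sphere with a k-nearest-neighbour adjacency graph, plus a set of
labelled subcortical structures.  The right hemisphere is an exact mirror
image (x -> -x) of the left, so left vertex ``i`` and right vertex
``mirror[i]`` form a homologous pair.

Vertex ordering is fixed: left cortex, right cortex, then subcortical
nodes.  All downstream maps and time series use this ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = ["BrainSpace", "make_space"]

LEFT, RIGHT = 0, 1


@dataclass
class BrainSpace:
    """Geometry of the synthetic analysis domain.

    Attributes
    ----------
    coords : (n_cortical, 3) float array
        Unit-sphere coordinates of the cortical vertices (both hemispheres).
    hemisphere : (n_cortical,) int array
        0 for left, 1 for right.
    neighbors : list of int arrays
        Symmetric adjacency lists for the cortical vertices.  Edges never
        cross the midline, so each hemisphere is its own connected graph.
    subcortical_labels : (n_subcortical,) int array
        Structure label (1..S) of each subcortical node.  Subcortical nodes
        occupy indices ``n_cortical .. n_cortical + n_subcortical - 1`` of
        the full grayordinate ordering.
    mirror : (n_per_hemisphere,) int array
        ``mirror[i]`` is the right-hemisphere counterpart of left vertex
        ``i`` (a bijection between hemispheres).
    """

    coords: np.ndarray
    hemisphere: np.ndarray
    neighbors: list[np.ndarray]
    subcortical_labels: np.ndarray
    mirror: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_per_hemisphere(self) -> int:
        return int(self.mirror.shape[0])

    @property
    def n_cortical(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_subcortical(self) -> int:
        return int(self.subcortical_labels.shape[0])

    @property
    def n_vertices(self) -> int:
        """Total grayordinates: cortical vertices plus subcortical nodes."""
        return self.n_cortical + self.n_subcortical

    @property
    def n_structures(self) -> int:
        return int(self.subcortical_labels.max()) if self.n_subcortical else 0

    def hemisphere_vertices(self, hemi: int) -> np.ndarray:
        return np.nonzero(self.hemisphere == hemi)[0]

    def structure_members(self, label: int) -> np.ndarray:
        """Full-space indices of the nodes of one subcortical structure."""
        local = np.nonzero(self.subcortical_labels == label)[0]
        return local + self.n_cortical

    def structure_indicators(self) -> np.ndarray:
        """(n_structures, n_vertices) binary membership maps."""
        out = np.zeros((self.n_structures, self.n_vertices))
        for s in range(1, self.n_structures + 1):
            out[s - 1, self.structure_members(s)] = 1.0
        return out

    def adjacency_matrix(self, vertices: np.ndarray | None = None) -> csr_matrix:
        """Sparse cortical adjacency, optionally restricted to a vertex subset."""
        rows, cols = [], []
        for i, nb in enumerate(self.neighbors):
            rows.extend([i] * len(nb))
            cols.extend(nb.tolist())
        a = csr_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(self.n_cortical, self.n_cortical),
        )
        if vertices is not None:
            a = a[vertices][:, vertices]
        return a


def _sphere_points(n: int, rng: np.random.Generator) -> np.ndarray:
    pts = rng.standard_normal((n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def _knn_edges(coords: np.ndarray, k: int) -> set[tuple[int, int]]:
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k + 1)
    edges: set[tuple[int, int]] = set()
    for i in range(coords.shape[0]):
        for j in idx[i, 1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            edges.add((a, b))
    return edges


def _connect(coords: np.ndarray, edges: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Add shortest bridging edges until the graph is a single component."""
    n = coords.shape[0]
    while True:
        rows = [e[0] for e in edges] + [e[1] for e in edges]
        cols = [e[1] for e in edges] + [e[0] for e in edges]
        a = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        n_comp, labels = connected_components(a, directed=False)
        if n_comp == 1:
            return edges
        # bridge the first component to its nearest outside vertex
        inside = np.nonzero(labels == 0)[0]
        outside = np.nonzero(labels != 0)[0]
        d = np.linalg.norm(coords[inside][:, None, :] - coords[outside][None, :, :], axis=2)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        a_, b_ = int(inside[i]), int(outside[j])
        edges.add((min(a_, b_), max(a_, b_)))


def make_space(
    n_vertices_per_hemisphere: int = 1000,
    n_subcortical_structures: int = 32,
    seed: int = 0,
    *,
    k_neighbors: int = 6,
    nodes_per_structure: int = 5,
) -> BrainSpace:
    """Build a synthetic grayordinate space.

    Left-hemisphere vertices are sampled uniformly on the unit sphere; the
    right hemisphere is their exact mirror image, so both hemispheres share
    one adjacency structure and the mirror map is ``i -> n + i``.

    Parameters
    ----------
    n_vertices_per_hemisphere : int
        Cortical vertices per hemisphere (>= 50).
    n_subcortical_structures : int
        Number of labelled subcortical structures (>= 1).
    k_neighbors : int
        Neighbours per vertex in the k-NN surface graph.
    nodes_per_structure : int
        Subcortical nodes per structure.
    """
    if n_vertices_per_hemisphere < 50:
        raise ValueError("n_vertices_per_hemisphere must be >= 50")
    if n_subcortical_structures < 1:
        raise ValueError("n_subcortical_structures must be >= 1")

    rng = np.random.default_rng(seed)
    n = n_vertices_per_hemisphere
    left = _sphere_points(n, rng)
    right = left * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])
    hemisphere = np.concatenate([np.full(n, LEFT), np.full(n, RIGHT)])

    edges = _connect(left, _knn_edges(left, k_neighbors))
    neighbors: list[list[int]] = [[] for _ in range(2 * n)]
    for a, b in edges:
        neighbors[a].append(b)
        neighbors[b].append(a)
        neighbors[n + a].append(n + b)
        neighbors[n + b].append(n + a)
    nb_arrays = [np.array(sorted(nb), dtype=np.int64) for nb in neighbors]

    labels = np.repeat(
        np.arange(1, n_subcortical_structures + 1), nodes_per_structure
    ).astype(np.int64)
    mirror = np.arange(n, 2 * n, dtype=np.int64)

    return BrainSpace(
        coords=coords,
        hemisphere=hemisphere,
        neighbors=nb_arrays,
        subcortical_labels=labels,
        mirror=mirror,
        meta={
            "seed": int(seed),
            "k_neighbors": int(k_neighbors),
            "nodes_per_structure": int(nodes_per_structure),
        },
    )
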