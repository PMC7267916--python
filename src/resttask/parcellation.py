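"""Random contiguous Voronoi parcellation of the cortical surface.

One predictor is later fit per parcel, so parcels only need to be
contiguous patches — they deliberately carry no functional or anatomical
meaning.  Seeds are drawn uniformly over vertices within each hemisphere
and every vertex joins its geodesically nearest seed (unweighted
graph-hop distance on the surface adjacency, ties to the lower seed
index).  Subcortical nodes are not tessellated; each labelled structure
forms its own parcel appended after the cortical ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .space import BrainSpace

__all__ = ["Parcellation", "voronoi_parcellate"]


@dataclass
class Parcellation:
    """Vertex -> parcel assignment over the full grayordinate space.

    Cortical parcels come first (left hemisphere, then right), followed by
    one parcel per subcortical structure.
    """

    labels: np.ndarray  # (n_vertices,) int parcel id
    n_per_hemisphere: int
    seed_vertices: np.ndarray  # cortical Voronoi seed vertex ids
    n_cortical_parcels: int
    n_parcels: int
    meta: dict = field(default_factory=dict)

    def members(self, parcel: int) -> np.ndarray:
        return np.nonzero(self.labels == parcel)[0]

    def parcel_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_parcels)


def _grow_parcels(neighbors: list[np.ndarray], vertices: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Multi-source BFS over a vertex subset; ties go to the lower seed index.

    Expanding seeds in index order within each BFS ring makes the
    tie-break deterministic and keeps every parcel a connected subgraph.
    """
    local = {int(v): i for i, v in enumerate(vertices)}
    label = np.full(len(vertices), -1, dtype=np.int64)
    frontiers: list[list[int]] = []
    for s_idx, s in enumerate(seeds):
        label[local[int(s)]] = s_idx
        frontiers.append([int(s)])
    n_assigned = len(seeds)
    while n_assigned < len(vertices):
        new_frontiers: list[list[int]] = []
        for s_idx, frontier in enumerate(frontiers):
            nxt: list[int] = []
            for v in frontier:
                for w in neighbors[v]:
                    wl = local.get(int(w))
                    if wl is not None and label[wl] == -1:
                        label[wl] = s_idx
                        nxt.append(int(w))
                        n_assigned += 1
            new_frontiers.append(nxt)
        frontiers = new_frontiers
        if all(len(f) == 0 for f in frontiers) and n_assigned < len(vertices):
            raise RuntimeError("hemisphere graph is not connected")
    return label


def voronoi_parcellate(space: BrainSpace, n_per_hemisphere: int = 50, seed: int = 0) -> Parcellation:
    """Tessellate each hemisphere into ``n_per_hemisphere`` random parcels.

    Parameters
    ----------
    space : BrainSpace
    n_per_hemisphere : int
        Parcels per hemisphere; must not exceed the hemisphere vertex count.
    seed : int
        Controls the random seed vertices; identical seeds reproduce the
        identical parcellation.
    """
    n_h = space.n_per_hemisphere
    if not 1 <= n_per_hemisphere <= n_h:
        raise ValueError(
            f"n_per_hemisphere must be in [1, {n_h}], got {n_per_hemisphere}"
        )
    rng = np.random.default_rng(seed)
    labels = np.full(space.n_vertices, -1, dtype=np.int64)
    all_seeds = []
    for hemi in (0, 1):
        verts = space.hemisphere_vertices(hemi)
        seeds = np.sort(rng.choice(verts, size=n_per_hemisphere, replace=False))
        all_seeds.append(seeds)
        local_label = _grow_parcels(space.neighbors, verts, seeds)
        labels[verts] = local_label + hemi * n_per_hemisphere
    n_cort = 2 * n_per_hemisphere
    for s in range(1, space.n_structures + 1):
        labels[space.structure_members(s)] = n_cort + s - 1
    return Parcellation(
        labels=labels,
        n_per_hemisphere=n_per_hemisphere,
        seed_vertices=np.concatenate(all_seeds),
        n_cortical_parcels=n_cort,
        n_parcels=n_cort + space.n_structures,
        meta={"seed": int(seed)},
    )
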