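"""Neuron skeletons: a tree of nodes parametrised by arc length from the soma.

A skeleton is the 1-voxel-wide centreline of a neurite, used to express
punctum positions as a normalised coordinate along the neuron (0 = soma,
1 = furthest terminal).  Skeletons are exchanged as SWC files, the format
used by common neuron-tracing tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Skeleton", "load_skeleton", "skeletonize_tube_mask"]

_SWC_SOMA_TYPE = 1


@dataclass
class Skeleton:
    """A connected tree of skeleton nodes with per-node arc length.

    Parameters
    ----------
    coords:
        ``(n, 3)`` node coordinates in voxel units, axis order ``(z, y, x)``.
    parents:
        Index of each node's parent in ``coords`` (``-1`` for the root).
    soma_index:
        Index of the soma node; arc lengths are measured from here.
    spacing:
        Physical voxel size (µm) per axis used for arc-length and distance
        computations.
    """

    coords: np.ndarray
    parents: np.ndarray
    soma_index: int = 0
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    node_ids: np.ndarray | None = None

    arc_length: np.ndarray = field(init=False)
    total_length: float = field(init=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        n = len(self.coords)
        if n == 0:
            raise ValueError("skeleton has no nodes")
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3) in (z, y, x) order")
        if self.node_ids is None:
            self.node_ids = np.arange(1, n + 1)
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        self._validate_tree(int(roots[0]))
        self.arc_length = self._arc_lengths()
        self.total_length = float(self.arc_length.max())

    def _validate_tree(self, root: int) -> None:
        n = len(self.coords)
        children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                children[p].append(i)
        seen = np.zeros(n, dtype=bool)
        stack = [root]
        while stack:
            i = stack.pop()
            if seen[i]:
                raise ValueError("skeleton contains a cycle")
            seen[i] = True
            stack.extend(children[i])
        if not seen.all():
            raise ValueError("skeleton is disconnected")
        self._children = children
        self._root = root

    def _arc_lengths(self) -> np.ndarray:
        # Edge lengths honour anisotropic spacing; arc length measured from
        # the soma node by traversal over the (undirected) tree.
        sp = np.asarray(self.spacing, dtype=float)
        n = len(self.coords)
        adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parents):
            if p >= 0:
                d = float(np.linalg.norm((self.coords[i] - self.coords[p]) * sp))
                adj[i].append((p, d))
                adj[p].append((i, d))
        arc = np.full(n, np.nan)
        arc[self.soma_index] = 0.0
        stack = [self.soma_index]
        while stack:
            i = stack.pop()
            for j, d in adj[i]:
                if np.isnan(arc[j]):
                    arc[j] = arc[i] + d
                    stack.append(j)
        return arc

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def terminal_indices(self) -> np.ndarray:
        """Nodes with no children (tree leaves)."""
        return np.array(
            [i for i in range(self.n_nodes) if not self._children[i] and i != self._root]
            or [self._root]
        )

    def physical_coords(self) -> np.ndarray:
        return self.coords * np.asarray(self.spacing)

    def nearest_node(self, points: np.ndarray) -> np.ndarray:
        """Index of the Euclidean-nearest node for each (z, y, x) voxel point.

        Distances are physical (spacing-weighted).  Exact ties are broken
        toward the node nearer the soma, which makes the mapping
        deterministic for points equidistant between two nodes.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        sp = np.asarray(self.spacing)
        node_xyz = self.coords * sp
        # ranking by (distance, arc length) implements the soma-ward tie-break
        d2 = ((points[:, None, :] * sp - node_xyz[None, :, :]) ** 2).sum(axis=2)
        d2 = np.round(d2, decimals=9)
        order = np.lexsort((self.arc_length[None, :].repeat(len(points), 0), d2), axis=1)
        return order[:, 0]

    def to_swc_rows(self) -> list[tuple]:
        """Rows in SWC column order (id, type, x, y, z, radius, parent)."""
        rows = []
        for i in range(self.n_nodes):
            parent = -1 if self.parents[i] < 0 else int(self.node_ids[self.parents[i]])
            ntype = _SWC_SOMA_TYPE if i == self.soma_index else 3
            z, y, x = self.coords[i]
            rows.append((int(self.node_ids[i]), ntype, x, y, z, 1.0, parent))
        return rows


def load_skeleton(
    path, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> Skeleton:
    """Parse an SWC file into a :class:`Skeleton`.

    The root node is treated as the soma unless a node of SWC type 1 (soma)
    exists, in which case that node is used.  Files with several roots,
    cycles or disconnected nodes are rejected.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["id", "type", "x", "y", "z", "radius", "parent"],
    )
    if df.empty:
        raise ValueError(f"SWC file {path} contains no nodes")
    ids = df["id"].to_numpy(dtype=int)
    index_of = {nid: i for i, nid in enumerate(ids)}
    parents = np.array(
        [-1 if p == -1 else index_of.get(int(p), -2) for p in df["parent"]], dtype=int
    )
    if (parents == -2).any():
        raise ValueError("SWC parent id not present in file")
    coords = df[["z", "y", "x"]].to_numpy(dtype=float)
    soma_rows = np.flatnonzero(df["type"].to_numpy(dtype=int) == _SWC_SOMA_TYPE)
    roots = np.flatnonzero(parents < 0)
    if len(roots) != 1:
        raise ValueError(f"SWC file must have exactly one root, found {len(roots)}")
    soma_index = int(soma_rows[0]) if len(soma_rows) else int(roots[0])
    return Skeleton(
        coords=coords,
        parents=parents,
        soma_index=soma_index,
        spacing=spacing,
        node_ids=ids,
    )


def skeletonize_tube_mask(
    mask: np.ndarray, spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> Skeleton:
    """Extract an unbranched skeleton from a tube-like binary mask.

    Intended for the generator's synthetic tubes: the mask is thinned to a
    centreline, the centreline voxels are chained into the longest path, and
    the resulting polyline becomes the skeleton.  Neurons with loops or
    heavy branching need a dedicated tracing tool instead.
    """
    from scipy.sparse.csgraph import shortest_path
    from scipy.spatial import cKDTree
    from skimage.morphology import skeletonize

    thin = skeletonize(mask.astype(bool))
    pts = np.argwhere(thin)
    if len(pts) == 0:
        raise ValueError("mask skeletonized to nothing")
    if len(pts) == 1:
        return Skeleton(coords=pts.astype(float), parents=np.array([-1]), spacing=spacing)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=float(np.sqrt(3) + 1e-6), output_type="ndarray")
    from scipy.sparse import csr_matrix

    w = np.linalg.norm((pts[pairs[:, 0]] - pts[pairs[:, 1]]) * np.asarray(spacing), axis=1)
    n = len(pts)
    graph = csr_matrix(
        (np.r_[w, w], (np.r_[pairs[:, 0], pairs[:, 1]], np.r_[pairs[:, 1], pairs[:, 0]])),
        shape=(n, n),
    )
    # two sweeps of Dijkstra find the (approximate) longest geodesic path
    d0 = shortest_path(graph, indices=0)
    a = int(np.nanargmax(np.where(np.isinf(d0), np.nan, d0)))
    da, pred = shortest_path(graph, indices=a, return_predecessors=True)
    b = int(np.nanargmax(np.where(np.isinf(da), np.nan, da)))
    path = [b]
    while path[-1] != a and pred[path[-1]] >= 0:
        path.append(int(pred[path[-1]]))
    order = path[::-1]
    coords = pts[order].astype(float)
    parents = np.r_[-1, np.arange(len(order) - 1)]
    return Skeleton(coords=coords, parents=parents, spacing=spacing)
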