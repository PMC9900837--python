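"""Rooted neuron skeletons and SWC I/O.

A :class:`Skeleton` is a rooted tree of 3-D vertices with radii, stored as
flat numpy arrays indexed by vertex (0..n-1).  The root is the soma vertex.
Per-vertex structural labels (soma / axon / dendrite / pruned) use the SWC
type codes; dendritic compartment labels (soma / proximal / distal basal /
apical) are assigned by the compartment pipeline and carried separately.

Coordinates are micrometres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# SWC structure-type codes used for per-vertex labels.
SWC_SOMA = 1
SWC_AXON = 2
SWC_DENDRITE = 3
SWC_PRUNED = 7

# Compartment codes for non-axon, non-pruned vertices.
COMP_NONE = -1
COMP_SOMA = 0
COMP_PROXIMAL = 1
COMP_DISTAL_BASAL = 2
COMP_APICAL = 3

COMPARTMENT_NAMES = {
    COMP_NONE: "none",
    COMP_SOMA: "soma",
    COMP_PROXIMAL: "proximal",
    COMP_DISTAL_BASAL: "distal_basal",
    COMP_APICAL: "apical",
}
COMPARTMENT_CODES = {v: k for k, v in COMPARTMENT_NAMES.items()}

# Synapse-table compartment vocabulary: the four dendritic compartments plus
# the pooled fifth compartment for synapses onto inhibitory cells.
COMPARTMENTS = ("soma", "proximal", "distal_basal", "apical", "inhibitory")


class SkeletonError(ValueError):
    """Malformed skeleton (multiple roots, cycles, dangling parents...)."""


@dataclass
class Segment:
    """An unbranched run of skeleton edges.

    ``vertices`` lists member vertices proximal-to-distal; each owns the edge
    to its parent, so the segment's proximal anchor (a branch point or the
    root) is *not* a member.  ``path_length`` is the summed member edge
    length.  ``is_terminal`` marks segments ending at a leaf.
    """

    vertices: np.ndarray
    path_length: float
    is_terminal: bool


class Skeleton:
    """Rooted tree of 3-D vertices with radii and labels.

    Parameters
    ----------
    positions : (n, 3) float array, micrometres.
    parent : (n,) int array; ``-1`` marks the single root.
    radius : (n,) float array, micrometres.
    vertex_label : (n,) int array of SWC type codes; defaults to dendrite,
        with the root set to soma.
    """

    def __init__(self, positions, parent, radius=None, vertex_label=None):
        self.positions = np.asarray(positions, dtype=float).reshape(-1, 3)
        self.parent = np.asarray(parent, dtype=np.int64)
        n = len(self.parent)
        if self.positions.shape[0] != n:
            raise SkeletonError("positions and parent length mismatch")
        if radius is None:
            radius = np.ones(n)
        self.radius = np.asarray(radius, dtype=float)
        if vertex_label is None:
            vertex_label = np.full(n, SWC_DENDRITE, dtype=np.int64)
        self.vertex_label = np.asarray(vertex_label, dtype=np.int64).copy()
        self.compartment = np.full(n, COMP_NONE, dtype=np.int64)

        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise SkeletonError(
                f"skeleton must have exactly one root, found {len(roots)}"
            )
        self.root = int(roots[0])
        self.vertex_label[self.root] = SWC_SOMA
        if np.any(self.parent >= n):
            raise SkeletonError("dangling parent reference")
        self._validate_tree()
        self._order = None
        self._children = None
        self._dist_to_root = None

    # -- structure ---------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.parent)

    def _validate_tree(self):
        # Every vertex must reach the root without revisiting (no cycles).
        n = self.n_vertices
        state = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 on path, 2 done
        state[self.root] = 2
        for v in range(n):
            path = []
            u = v
            while state[u] == 0:
                state[u] = 1
                path.append(u)
                u = int(self.parent[u])
            if state[u] == 1:
                raise SkeletonError("parent links contain a cycle")
            for p in path:
                state[p] = 2

    @property
    def children(self) -> list[np.ndarray]:
        if self._children is None:
            idx = np.argsort(self.parent[self.parent >= 0], kind="stable")
            kids = np.flatnonzero(self.parent >= 0)[idx]
            order = self.parent[kids]
            splits = np.searchsorted(order, np.arange(self.n_vertices + 1))
            self._children = [
                kids[splits[i]:splits[i + 1]] for i in range(self.n_vertices)
            ]
        return self._children

    @property
    def topological_order(self) -> np.ndarray:
        """Vertices in root-first (BFS) order; parents precede children."""
        if self._order is None:
            order = np.empty(self.n_vertices, dtype=np.int64)
            order[0] = self.root
            head, tail = 0, 1
            kids = self.children
            while head < tail:
                for c in kids[order[head]]:
                    order[tail] = c
                    tail += 1
                head += 1
            self._order = order
        return self._order

    @property
    def edge_lengths(self) -> np.ndarray:
        """Length of the edge from each vertex to its parent (0 at root)."""
        lengths = np.zeros(self.n_vertices)
        nz = self.parent >= 0
        lengths[nz] = np.linalg.norm(
            self.positions[nz] - self.positions[self.parent[nz]], axis=1
        )
        return lengths

    @property
    def dist_to_root(self) -> np.ndarray:
        if self._dist_to_root is None:
            d = np.zeros(self.n_vertices)
            el = self.edge_lengths
            for v in self.topological_order[1:]:
                d[v] = d[self.parent[v]] + el[v]
            self._dist_to_root = d
        return self._dist_to_root

    def path_distance(self, a: int, b: int) -> float:
        """Path length between two vertices along the unique tree path."""
        n = self.n_vertices
        if not (0 <= a < n and 0 <= b < n):
            raise SkeletonError(f"vertex not in skeleton: {a if a >= n or a < 0 else b}")
        d = self.dist_to_root
        # Walk the deeper endpoint up until the paths merge.
        seen = {}
        u = a
        while u != -1:
            seen[u] = True
            u = int(self.parent[u])
        u = b
        while u not in seen:
            u = int(self.parent[u])
        return float(d[a] + d[b] - 2.0 * d[u])

    def subtree_mask(self, v: int) -> np.ndarray:
        """Boolean mask of vertices in the subtree rooted at ``v`` (inclusive)."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        mask[v] = True
        for u in self.topological_order[1:]:
            if mask[self.parent[u]]:
                mask[u] = True
        mask[v] = True
        return mask

    def branch_points(self) -> np.ndarray:
        n_child = np.bincount(
            self.parent[self.parent >= 0], minlength=self.n_vertices
        )
        return np.flatnonzero(n_child >= 2)

    def leaves(self) -> np.ndarray:
        n_child = np.bincount(
            self.parent[self.parent >= 0], minlength=self.n_vertices
        )
        mask = n_child == 0
        mask[self.root] = False
        return np.flatnonzero(mask)

    def root_branches(self, mask=None) -> list[np.ndarray]:
        """Subtrees hanging off the root, as vertex arrays.

        ``mask`` optionally restricts to vertices where it is True (e.g. the
        dendritic region); branches whose root-child is masked out are skipped.
        """
        out = []
        for c in self.children[self.root]:
            if mask is not None and not mask[c]:
                continue
            sub = self.subtree_mask(int(c))
            if mask is not None:
                sub &= mask
            out.append(np.flatnonzero(sub))
        return out

    # -- segments ----------------------------------------------------------

    def decompose_segments(self, mask=None) -> list[Segment]:
        """Partition edges into unbranched segments.

        Segments run between consecutive branch points, or between a branch
        point (or the root) and an end point.  With ``mask``, only vertices
        where the mask is True participate; mask boundaries act as segment
        boundaries.
        """
        n = self.n_vertices
        if mask is None:
            mask = np.ones(n, dtype=bool)
        in_region = np.asarray(mask, dtype=bool)
        n_child = np.zeros(n, dtype=np.int64)
        for v in range(n):
            p = self.parent[v]
            if p >= 0 and in_region[v] and in_region[p]:
                n_child[p] += 1
        el = self.edge_lengths
        segments = []
        # Segment ends: in-region vertices that are leaves or branch points
        # (with respect to the region).
        for v in range(n):
            if not in_region[v] or v == self.root:
                continue
            if n_child[v] != 0 and n_child[v] < 2:
                continue
            # v ends a segment; walk up through pass-through vertices.
            verts = [v]
            u = int(self.parent[v])
            while (
                u >= 0
                and in_region[u]
                and u != self.root
                and n_child[u] == 1
            ):
                verts.append(u)
                u = int(self.parent[u])
            verts = np.array(verts[::-1], dtype=np.int64)
            # Only count edges whose parent endpoint is in-region.
            keep = in_region[self.parent[verts]] & (self.parent[verts] >= 0)
            length = float(el[verts][keep].sum())
            segments.append(
                Segment(
                    vertices=verts,
                    path_length=length,
                    is_terminal=bool(n_child[v] == 0),
                )
            )
        return segments

    def total_cable_length(self, mask=None) -> float:
        el = self.edge_lengths
        if mask is None:
            return float(el.sum())
        m = np.asarray(mask, dtype=bool)
        keep = m.copy()
        keep[self.parent < 0] = False
        ok = np.zeros_like(keep)
        nz = self.parent >= 0
        ok[nz] = m[nz] & m[self.parent[nz]]
        return float(el[ok].sum())

    # -- labels ------------------------------------------------------------

    def dendrite_mask(self) -> np.ndarray:
        """Non-axon, non-pruned vertices (includes the soma root)."""
        return (self.vertex_label != SWC_AXON) & (self.vertex_label != SWC_PRUNED)

    def copy(self) -> "Skeleton":
        sk = Skeleton(
            self.positions.copy(),
            self.parent.copy(),
            self.radius.copy(),
            self.vertex_label.copy(),
        )
        sk.compartment = self.compartment.copy()
        return sk

    # -- SWC I/O -----------------------------------------------------------

    @classmethod
    def from_swc(cls, path) -> "Skeleton":
        """Read a standard 7-column SWC file.

        Vertex ids are remapped to 0..n-1 in file order; column 2 (type)
        populates ``vertex_label``.
        """
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SkeletonError(f"malformed SWC line in {path}: {line!r}")
            rows.append(parts)
        if not rows:
            raise SkeletonError(f"empty SWC file: {path}")
        ids = np.array([int(r[0]) for r in rows])
        if len(np.unique(ids)) != len(ids):
            raise SkeletonError(f"duplicate vertex ids in {path}")
        idmap = {int(i): k for k, i in enumerate(ids)}
        label = np.array([int(r[1]) for r in rows])
        pos = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
        radius = np.array([float(r[5]) for r in rows])
        parent_raw = [int(r[6]) for r in rows]
        parent = np.empty(len(rows), dtype=np.int64)
        for k, p in enumerate(parent_raw):
            if p == -1:
                parent[k] = -1
            else:
                if p not in idmap:
                    raise SkeletonError(f"dangling parent id {p} in {path}")
                parent[k] = idmap[p]
        n_roots = int((parent == -1).sum())
        if n_roots != 1:
            raise SkeletonError(
                f"multiple roots in {path}" if n_roots > 1 else f"no root in {path}"
            )
        return cls(pos, parent, radius, label)

    def to_swc(self, path) -> None:
        """Write standard SWC with sequential ids 1..n."""
        lines = ["# id type x y z radius parent"]
        for v in range(self.n_vertices):
            p = self.parent[v]
            lines.append(
                "%d %d %.6f %.6f %.6f %.6f %d"
                % (
                    v + 1,
                    self.vertex_label[v],
                    self.positions[v, 0],
                    self.positions[v, 1],
                    self.positions[v, 2],
                    self.radius[v],
                    p + 1 if p >= 0 else -1,
                )
            )
        Path(path).write_text("\n".join(lines) + "\n")
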