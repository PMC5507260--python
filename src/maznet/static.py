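"""Static behavioral networks over a fixed 25-node zone tessellation of the arena.

Twenty-five nodes are scattered uniformly across the arena disk — one at the
center, 8 on a mid ring at half the arena radius, and 16 on an outer ring at
0.85 of the arena radius (first node of each ring at the canonical 45-degree
diagonal, so the outer ring resolves all 12 holes). Each node's zone is its
nearest-node (Voronoi) cell clipped to the disk, and the resulting network is
planar: links are only permitted between nodes whose zones share a boundary.
A trial's point sequence is converted to the sequence of nearest nodes, and
consecutive distinct nodes contribute links; a frame-to-frame jump across
non-adjacent zones is decomposed into the chain of zones the straight segment
crosses, preserving planarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Voronoi

from maznet.arena import ArenaSpec, ring_point, TARGET_ANGLE
from maznet.network import BehaviorNetwork
from maznet.trajectory import Trajectory


@dataclass
class StaticLayout:
    """The fixed node set, its implicit zone partition, and allowed adjacency.

    ``adjacency_allowed[i, j]`` is True when zones i and j share a boundary
    segment inside the arena (symmetric, zero diagonal). The zone of a point
    is simply its nearest node, so the layout needs no explicit polygon
    representation.
    """

    nodes: np.ndarray  # (25, 2)
    adjacency_allowed: np.ndarray  # (25, 25) bool
    arena_center: tuple[float, float]
    arena_radius: float

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 2)
        self.adjacency_allowed = np.asarray(self.adjacency_allowed, dtype=bool)
        if not np.array_equal(self.adjacency_allowed, self.adjacency_allowed.T):
            raise ValueError("adjacency_allowed must be symmetric")
        if np.any(np.diag(self.adjacency_allowed)):
            raise ValueError("adjacency_allowed must have zero diagonal")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def nearest(self, points: np.ndarray) -> np.ndarray:
        """Zone (node) id of each point; ties go to the lowest node id."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(pts[:, None, :] - self.nodes[None, :, :], axis=2)
        return np.argmin(d, axis=1)

    @classmethod
    def from_json(cls, path, spec: ArenaSpec) -> "StaticLayout":
        """Load a layout from JSON: {"nodes": [[x,y],...], "adjacency": [[i,j],...]?}.

        When no explicit adjacency is given it is derived from the Voronoi
        diagram of the nodes clipped to the arena disk.
        """
        with open(path) as fh:
            data = json.load(fh)
        nodes = np.asarray(data["nodes"], dtype=float)
        if "adjacency" in data and data["adjacency"] is not None:
            adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
            for i, j in data["adjacency"]:
                adj[i, j] = adj[j, i] = True
            np.fill_diagonal(adj, False)
        else:
            adj = _voronoi_adjacency(nodes, spec.center, spec.arena_radius)
        return cls(nodes=nodes, adjacency_allowed=adj,
                   arena_center=spec.center, arena_radius=spec.arena_radius)


def _voronoi_adjacency(nodes: np.ndarray, center, radius: float) -> np.ndarray:
    """Zone adjacency from the Voronoi diagram, clipped to the arena disk.

    Two zones share a boundary iff their Voronoi ridge intersects the open
    disk. Infinite ridges are truncated far outside the arena before the
    distance test.
    """
    vor = Voronoi(nodes)
    c = np.asarray(center, dtype=float)
    n = len(nodes)
    adj = np.zeros((n, n), dtype=bool)
    ptp = float(np.ptp(nodes, axis=0).max())
    far = 100.0 * max(ptp, radius)
    pcenter = nodes.mean(axis=0)
    for (p1, p2), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in ridge:
            # semi-infinite ridge: direction is perpendicular to p1-p2,
            # pointing away from the point cloud center
            (v_idx,) = [v for v in ridge if v != -1]
            a = vor.vertices[v_idx]
            tangent = nodes[p2] - nodes[p1]
            tangent = tangent / np.linalg.norm(tangent)
            normal = np.array([-tangent[1], tangent[0]])
            midpoint = (nodes[p1] + nodes[p2]) / 2
            if np.dot(midpoint - pcenter, normal) < 0:
                normal = -normal
            b = a + far * normal
        else:
            a, b = vor.vertices[ridge[0]], vor.vertices[ridge[1]]
        if _segment_min_dist(a, b, c) < radius:
            adj[p1, p2] = adj[p2, p1] = True
    return adj


def _segment_min_dist(a: np.ndarray, b: np.ndarray, p: np.ndarray) -> float:
    ab = b - a
    denom = float(np.dot(ab, ab))
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    s = np.clip(np.dot(p - a, ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(a + s * ab - p))


def default_static_layout(spec: ArenaSpec) -> StaticLayout:
    """The default 1 + 8 + 16 ring layout of 25 static nodes.

    One node at the arena center, 8 equally spaced at ``arena_radius / 2`` and
    16 equally spaced at ``0.85 * arena_radius``; the first node of each ring
    sits on the 45-degree target diagonal.
    """
    pts = [np.asarray(spec.center, dtype=float)]
    for count, radius in ((8, spec.arena_radius / 2), (16, 0.85 * spec.arena_radius)):
        for k in range(count):
            angle = TARGET_ANGLE + 2 * np.pi * k / count
            pts.append(ring_point(spec, angle, radius))
    nodes = np.array(pts)
    adj = _voronoi_adjacency(nodes, spec.center, spec.arena_radius)
    return StaticLayout(nodes=nodes, adjacency_allowed=adj,
                        arena_center=spec.center, arena_radius=spec.arena_radius)


def node_sequence(traj: Trajectory, layout: StaticLayout) -> np.ndarray:
    """Per-frame id of the nearest static node."""
    return layout.nearest(traj.xy)


def _zone_chain(layout: StaticLayout, p0, p1, u: int, v: int, depth: int = 0) -> list[int]:
    """Ordered zone ids crossed by the straight segment p0->p1 (endpoints in u, v)."""
    if u == v:
        return [u]
    if layout.adjacency_allowed[u, v]:
        return [u, v]
    if depth >= 48:
        # numerically degenerate crossing (e.g. exactly through a zone corner)
        w = int(layout.nearest((np.asarray(p0) + np.asarray(p1)) / 2)[0])
        if w not in (u, v) and layout.adjacency_allowed[u, w] and layout.adjacency_allowed[w, v]:
            return [u, w, v]
        warnings.warn("could not resolve zone chain; transition dropped", stacklevel=2)
        return [u]
    mid = (np.asarray(p0, dtype=float) + np.asarray(p1, dtype=float)) / 2
    w = int(layout.nearest(mid)[0])
    left = _zone_chain(layout, p0, mid, u, w, depth + 1)
    right = _zone_chain(layout, mid, p1, w, v, depth + 1)
    return left + right[1:]


def build_static_network(
    traj_or_seq,
    layout: StaticLayout,
    xy: np.ndarray | None = None,
) -> BehaviorNetwork:
    """Build the planar static network of one trial.

    Accepts either a Trajectory or a precomputed node sequence with matching
    frame coordinates ``xy``. Consecutive distinct zone ids add an undirected
    link when their zones are adjacent; otherwise the straight segment between
    the two frames is decomposed into the chain of zones it crosses and links
    are added along the chain. Self-transitions add nothing; the resulting
    adjacency satisfies A <= adjacency_allowed elementwise.
    """
    if isinstance(traj_or_seq, Trajectory):
        seq = node_sequence(traj_or_seq, layout)
        xy = traj_or_seq.xy
    else:
        seq = np.asarray(traj_or_seq, dtype=int)
        if xy is None:
            xy = layout.nodes[seq]
    if len(seq) == 0:
        raise ValueError("empty node sequence")
    n = layout.n_nodes
    A = np.zeros((n, n), dtype=int)
    C = np.zeros((n, n), dtype=int)
    visited = np.zeros(n, dtype=bool)
    visited[seq[0]] = True
    for i in range(1, len(seq)):
        u, v = int(seq[i - 1]), int(seq[i])
        if u == v:
            continue
        chain = _zone_chain(layout, xy[i - 1], xy[i], u, v)
        for a, b in zip(chain[:-1], chain[1:]):
            if a == b:
                continue
            A[a, b] = A[b, a] = 1
            C[a, b] += 1
            C[b, a] += 1
            visited[a] = visited[b] = True
        visited[v] = True
    # restrict to visited zones so order n = number of distinct zones involved
    ids = np.nonzero(visited)[0]
    members = [[int(z)] for z in ids]
    return BehaviorNetwork(
        node_xy=layout.nodes[ids],
        adjacency=A[np.ix_(ids, ids)],
        transition_counts=C[np.ix_(ids, ids)],
        members=members,
        kind="static",
    )
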