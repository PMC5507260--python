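"""Stop-episode detection and dynamic (stop-derived) behavioral networks.

A stop is a low-displacement episode: whenever the path length within a
sliding window of ``stop_window`` successive frames falls below
``stop_threshold`` (default 20 px, about half a mouse body length, over 5
frames at 5 Hz), the animal is considered stopped. Overlapping qualifying
windows are merged into one maximal episode summarized by the centroid of its
frames. Stop centroids are then clustered into spatial nodes with the City
Clustering Algorithm (CCA), and consecutive stops visiting different nodes
contribute undirected links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from maznet.arena import ArenaSpec
from maznet.network import BehaviorNetwork, empty_network
from maznet.trajectory import Trajectory


@dataclass(frozen=True)
class StopEpisode:
    """One detected stop: the merged run of qualifying frames and its centroid."""

    start_frame: int
    end_frame: int  # inclusive
    centroid: tuple[float, float]

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def detect_stops(traj: Trajectory, spec: ArenaSpec) -> list[StopEpisode]:
    """Detect stop episodes in a trajectory.

    A window of ``spec.stop_window`` successive frames qualifies when the path
    length over its steps is below ``spec.stop_threshold``. Maximal runs of
    overlapping qualifying windows are merged into single episodes; each
    episode's stopping coordinate is the centroid of every frame it covers.
    Returns episodes ordered by start frame; empty list for trajectories
    shorter than the window.
    """
    w = spec.stop_window
    xy = traj.xy
    nf = len(xy)
    if nf < w:
        return []
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    # path length of window starting at i covers steps i .. i+w-2
    csum = np.concatenate([[0.0], np.cumsum(steps)])
    win = csum[w - 1:] - csum[:nf - w + 1]
    qual = win < spec.stop_threshold
    starts = np.nonzero(qual)[0]
    episodes: list[StopEpisode] = []
    k = 0
    while k < len(starts):
        first = starts[k]
        last = starts[k]
        # chain every later qualifying window that overlaps the run's frames
        while k + 1 < len(starts) and starts[k + 1] <= last + w - 1:
            k += 1
            last = starts[k]
        start, end = int(first), int(last + w - 1)
        centroid = xy[start:end + 1].mean(axis=0)
        episodes.append(StopEpisode(start, end, (float(centroid[0]), float(centroid[1]))))
        k += 1
    return episodes


def cca_cluster(
    points: np.ndarray,
    threshold: float,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Partition points into spatial nodes with the City Clustering Algorithm.

    Iterative refinement: sweep the points in their given (chronological)
    order, assigning each to the nearest current node if it lies within
    ``threshold``, otherwise spawning a new node at the point; after each
    sweep node centroids are recomputed as member means and empty nodes
    dropped. Sweeps repeat until the assignment is unchanged or ``max_iter``
    passes have run.

    Returns
    -------
    centroids : ndarray, shape (k, 2)
        Node coordinates (member means).
    labels : ndarray of int, shape (n,)
        Node id of every point; every point is assigned exactly once.
    converged : bool
        False when the assignment was still changing after ``max_iter`` passes.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("cca_cluster requires at least one point")

    centroids = np.empty((0, 2))
    labels = np.full(len(pts), -1, dtype=int)
    converged = False
    for _ in range(max_iter):
        new_labels = np.full(len(pts), -1, dtype=int)
        cents = [c for c in centroids]  # grows as new nodes spawn
        for i, p in enumerate(pts):
            if cents:
                d = np.linalg.norm(np.asarray(cents) - p, axis=1)
                j = int(np.argmin(d))
                if d[j] < threshold:
                    new_labels[i] = j
                    continue
            cents.append(p.copy())
            new_labels[i] = len(cents) - 1
        # recompute centroids from members; drop empty nodes, compact ids
        used = np.unique(new_labels)
        remap = {int(u): k for k, u in enumerate(used)}
        new_labels = np.array([remap[int(l)] for l in new_labels], dtype=int)
        centroids = np.array([pts[new_labels == k].mean(axis=0) for k in range(len(used))])
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
    return centroids, labels, converged


def build_local_network(stops: list[StopEpisode], spec: ArenaSpec) -> BehaviorNetwork:
    """Build a trial's dynamic network from its stop episodes.

    Stop centroids are clustered into nodes with the CCA at
    ``spec.cca_threshold``; each consecutive stop pair mapped to distinct
    nodes adds one undirected link (transition multiplicities are recorded;
    same-node transitions are ignored — no self-links). A trial with zero
    stops yields an empty network whose features are flagged undefined
    downstream.
    """
    if not stops:
        return empty_network("dynamic")
    pts = np.array([s.centroid for s in stops], dtype=float)
    centroids, labels, converged = cca_cluster(pts, spec.cca_threshold)
    if not converged:
        import warnings

        warnings.warn("CCA did not converge within the iteration limit", stacklevel=2)
    n = len(centroids)
    A = np.zeros((n, n), dtype=int)
    C = np.zeros((n, n), dtype=int)
    for u, v in zip(labels[:-1], labels[1:]):
        if u != v:
            A[u, v] = A[v, u] = 1
            C[u, v] += 1
            C[v, u] += 1
    members = [np.nonzero(labels == k)[0].tolist() for k in range(n)]
    return BehaviorNetwork(
        node_xy=centroids, adjacency=A, transition_counts=C,
        members=members, kind="dynamic",
    )
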