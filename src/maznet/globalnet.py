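"""Group-level global networks: CCA-merged local nodes with log-scaled magnitudes.

All local (per-trial) networks of one group on one day are aggregated: the
coordinates of every local node are clustered with the same City Clustering
Algorithm and distance threshold used for the local dynamic nodes, each local
node joining exactly one global node. A global link connects two global nodes
whenever some local link joins local nodes assigned to them; its weight counts
the supporting local links. Node magnitude is the natural log of the member
count (rendered with a minimum marker size so singleton nodes stay visible).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from maznet.arena import ArenaSpec
from maznet.dynamic import cca_cluster
from maznet.network import BehaviorNetwork


@dataclass
class GlobalNetwork:
    """A per-group-day aggregate of local behavioral networks."""

    network: BehaviorNetwork
    magnitudes: np.ndarray          # ln(member count) per global node
    member_map: list[list[tuple[int, int]]]  # per global node: (local net idx, local node id)
    group: str = ""
    day: int = 0

    @property
    def order(self) -> int:
        return self.network.order

    @property
    def degrees(self) -> np.ndarray:
        """Per-node link count M_i (binary degree)."""
        return self.network.adjacency.sum(axis=1)

    @property
    def member_counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.member_map], dtype=int)


def build_global(
    local_nets: list[BehaviorNetwork],
    spec: ArenaSpec,
    group: str = "",
    day: int = 0,
) -> GlobalNetwork:
    """Aggregate local networks into one global network.

    Empty local networks are skipped. Raises when no local node exists at all.
    """
    coords = []
    owners = []  # (local net index, local node id)
    for li, net in enumerate(local_nets):
        for ni in range(net.order):
            coords.append(net.node_xy[ni])
            owners.append((li, ni))
    if not coords:
        raise ValueError("no local nodes to aggregate")
    coords = np.asarray(coords)
    centroids, labels, _ = cca_cluster(coords, spec.cca_threshold)
    k = len(centroids)
    member_map: list[list[tuple[int, int]]] = [[] for _ in range(k)]
    lookup: dict[tuple[int, int], int] = {}
    for (owner, g) in zip(owners, labels):
        member_map[int(g)].append(owner)
        lookup[owner] = int(g)

    A = np.zeros((k, k), dtype=int)
    W = np.zeros((k, k), dtype=int)
    for li, net in enumerate(local_nets):
        ii, jj = np.nonzero(np.triu(net.adjacency, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g1, g2 = lookup[(li, i)], lookup[(li, j)]
            if g1 == g2:
                continue  # local link collapsed inside one global node
            A[g1, g2] = A[g2, g1] = 1
            W[g1, g2] += 1
            W[g2, g1] += 1

    network = BehaviorNetwork(
        node_xy=centroids, adjacency=A, transition_counts=W,
        members=[[i for i, _ in enumerate(m)] for m in member_map], kind="global",
    )
    magnitudes = np.log(np.array([len(m) for m in member_map], dtype=float))
    return GlobalNetwork(network=network, magnitudes=magnitudes,
                         member_map=member_map, group=group, day=day)


# degree color bins for the polar topology rendering: (min inclusive, color)
DEGREE_COLOR_BINS = (
    (12, "white"),
    (9, "yellow"),
    (6, "orange"),
    (3, "red"),
    (0, "brown"),
)


def degree_color(degree: int) -> str:
    """Color bin of a global node by its degree M_i."""
    for lo, color in DEGREE_COLOR_BINS:
        if degree >= lo:
            return color
    return "brown"


def polar_topology_layout(gnet: GlobalNetwork) -> list[dict]:
    """Degree-sorted polar layout of a global network.

    Nodes are sorted by degree M_i descending (ties broken by node id) and
    placed at angles linearly spaced from 0 to 360 degrees — the
    highest-degree node at 0, the lowest at 360. Each node is assigned its
    degree color bin. Returns one dict per node with keys
    ``node``, ``degree``, ``angle_deg``, ``color``.
    """
    if gnet.order == 0:
        raise ValueError("empty global network")
    deg = gnet.degrees
    order = sorted(range(gnet.order), key=lambda i: (-deg[i], i))
    if len(order) == 1:
        angles = [0.0]
    else:
        angles = np.linspace(0.0, 360.0, len(order)).tolist()
    return [
        {"node": int(i), "degree": int(deg[i]), "angle_deg": float(a),
         "color": degree_color(int(deg[i]))}
        for i, a in zip(order, angles)
    ]
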