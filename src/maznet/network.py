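"""The behavioral-network container shared by dynamic, static and global analyses.

A behavioral network is an undirected graph without self-links: nodes are
places in the arena (stop clusters, zone centers, or merged group-level
nodes) and a link records that at least one direct transition occurred
between two places during a trial. The adjacency used by all graph features
is binary; transition multiplicities are kept separately for visualization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class BehaviorNetwork:
    """Undirected behavioral network for one trial (local) or one group-day (global).

    Attributes
    ----------
    node_xy : ndarray, shape (n, 2)
        Node coordinates (px).
    adjacency : ndarray, shape (n, n)
        Symmetric binary adjacency with zero diagonal.
    transition_counts : ndarray, shape (n, n)
        Symmetric counts of observed transitions; positive exactly where
        adjacency is 1.
    members : list of list of int
        Per node, the ids of its members (stop indices for dynamic nodes,
        the zone id for static nodes, local-node ids for global nodes).
    kind : str
        "dynamic", "static" or "global".
    """

    node_xy: np.ndarray
    adjacency: np.ndarray
    transition_counts: np.ndarray
    members: list[list[int]] = field(default_factory=list)
    kind: str = "dynamic"

    def __post_init__(self) -> None:
        self.node_xy = np.asarray(self.node_xy, dtype=float).reshape(-1, 2)
        n = len(self.node_xy)
        self.adjacency = np.asarray(self.adjacency, dtype=int).reshape(n, n)
        self.transition_counts = np.asarray(self.transition_counts, dtype=int).reshape(n, n)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("self-links are not allowed")
        if np.any((self.transition_counts > 0) != (self.adjacency == 1)):
            raise ValueError("transition_counts must be positive exactly where adjacency is 1")
        if not self.members:
            self.members = [[i] for i in range(n)]

    @property
    def order(self) -> int:
        """Number of nodes n."""
        return len(self.node_xy)

    @property
    def n_links(self) -> int:
        """Number of undirected links m = (1/2) sum_ij A_ij."""
        return int(self.adjacency.sum() // 2)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i, (x, y) in enumerate(self.node_xy):
            g.add_node(i, x=float(x), y=float(y), n_members=len(self.members[i]))
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        for i, j in zip(ii.tolist(), jj.tolist()):
            g.add_edge(i, j, count=int(self.transition_counts[i, j]))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, kind: str = "dynamic") -> "BehaviorNetwork":
        """Build from a networkx graph; missing coordinates default to zero."""
        nodes = sorted(g.nodes)
        idx = {u: i for i, u in enumerate(nodes)}
        n = len(nodes)
        xy = np.array([[g.nodes[u].get("x", 0.0), g.nodes[u].get("y", 0.0)] for u in nodes],
                      dtype=float).reshape(n, 2)
        A = np.zeros((n, n), dtype=int)
        C = np.zeros((n, n), dtype=int)
        for u, v, data in g.edges(data=True):
            i, j = idx[u], idx[v]
            if i == j:
                continue
            A[i, j] = A[j, i] = 1
            C[i, j] = C[j, i] = int(data.get("count", 1))
        return cls(node_xy=xy, adjacency=A, transition_counts=C, kind=kind)

    # -- export -------------------------------------------------------------

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def write_edgelist_csv(self, node_path, edge_path) -> None:
        """Write nodes (id, x, y, n_members) and edges (u, v, count) as CSVs."""
        pd.DataFrame({
            "id": np.arange(self.order),
            "x": self.node_xy[:, 0],
            "y": self.node_xy[:, 1],
            "n_members": [len(m) for m in self.members],
        }).to_csv(node_path, index=False)
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        pd.DataFrame({
            "u": ii, "v": jj,
            "count": self.transition_counts[ii, jj],
        }).to_csv(edge_path, index=False)


def empty_network(kind: str) -> BehaviorNetwork:
    """A network with no nodes (trial with no stops); features are undefined."""
    return BehaviorNetwork(
        node_xy=np.empty((0, 2)),
        adjacency=np.empty((0, 0), dtype=int),
        transition_counts=np.empty((0, 0), dtype=int),
        members=[],
        kind=kind,
    )
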