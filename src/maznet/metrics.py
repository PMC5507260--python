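"""The eight behavioral-network features.

For a trial network with binary symmetric adjacency A (no self-links):

* number of stops ``o`` — stopping coordinates feeding the network (dynamic
  networks only; undefined for static/global networks);
* order ``n`` — node count;
* degree ``m/n`` — total link count m = (1/2) sum_ij A_ij divided by the
  order (note: half the conventional mean degree — the literal definition
  used by the source analysis; conventional 2m/n is also exported);
* density ``rho = 2m / (n (n-1))``;
* clustering coefficient ``C_WS`` — mean over nodes of C_i = R_i / (k_i - 1),
  where the redundancy R_i is the average number of links from a neighbor of
  i to other neighbors of i (algebraically 2 T_i / k_i with T_i the triangle
  count at i); nodes of degree < 2 are excluded from the mean;
* shortest path ``l`` — mean unweighted shortest-path length over unordered
  reachable pairs of distinct nodes;
* betweenness ``x`` — mean over nodes of the unnormalized centrality
  x_i = sum over ordered pairs s != t (both != i) of sigma_st(i) / g_st;
* closeness ``cl`` — mean over nodes of cl_i = 1 / sum_j d_ij (reachable j).

Every feature carries a defined flag so degenerate (empty or single-node)
networks propagate as undefined rather than as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from maznet.network import BehaviorNetwork

_UNDEF = float("nan")


@dataclass
class NetworkFeatures:
    """The eight features of one network, with per-feature defined flags."""

    n_stops: float
    order: int
    degree: float          # m / n (source definition)
    density: float
    clustering: float
    shortest_path: float
    betweenness: float
    closeness: float
    mean_degree: float = _UNDEF  # conventional 2m / n, for reference
    n_unreachable_pairs: int = 0
    defined: dict = field(default_factory=dict)

    FEATURES = ("n_stops", "order", "degree", "density", "clustering",
                "shortest_path", "betweenness", "closeness")

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.FEATURES}
        d["mean_degree"] = self.mean_degree
        return d


def _distances_and_sigma(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs BFS distances and shortest-path counts on a binary adjacency.

    Returns (D, S): D[i, j] is the unweighted shortest-path length (inf when
    unreachable), S[i, j] the number of distinct shortest i-j paths.
    """
    n = len(A)
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    neighbors = [np.nonzero(A[i])[0] for i in range(n)]
    for s in range(n):
        D[s, s] = 0
        S[s, s] = 1.0
        frontier = [s]
        d = 0
        while frontier:
            nxt: list[int] = []
            for u in frontier:
                for v in neighbors[u]:
                    if np.isinf(D[s, v]):
                        D[s, v] = d + 1
                        S[s, v] = S[s, u]
                        nxt.append(int(v))
                    elif D[s, v] == d + 1:
                        S[s, v] += S[s, u]
            frontier = nxt
            d += 1
    return D, S


def link_count(net: BehaviorNetwork) -> int:
    """m = (1/2) sum_ij A_ij."""
    return net.n_links


def degree_feature(net: BehaviorNetwork) -> float:
    """Links per node m / n; undefined (NaN) for an empty network."""
    if net.order == 0:
        return _UNDEF
    return net.n_links / net.order


def density(net: BehaviorNetwork) -> float:
    """rho = 2m / (n (n - 1)); undefined for n < 2."""
    n = net.order
    if n < 2:
        return _UNDEF
    return 2.0 * net.n_links / (n * (n - 1))


def redundancy(net: BehaviorNetwork, i: int) -> float:
    """R_i: average number of links from a neighbor of i to other neighbors of i."""
    A = net.adjacency
    nbrs = np.nonzero(A[i])[0]
    k = len(nbrs)
    if k == 0:
        return 0.0
    # per neighbor j: links from j to the other neighbors of i
    sub = A[np.ix_(nbrs, nbrs)]
    return float(sub.sum()) / k  # sub.sum() double-counts pairs = per-neighbor totals summed


def clustering_ws(net: BehaviorNetwork) -> tuple[float, int]:
    """Network clustering coefficient C_WS.

    Mean over nodes with degree >= 2 of C_i = R_i / (k_i - 1); returns
    ``(value, n_excluded)`` where excluded nodes have degree < 2. Undefined
    (NaN) when no node qualifies.
    """
    A = net.adjacency
    deg = A.sum(axis=1)
    cs = []
    for i in range(net.order):
        k = int(deg[i])
        if k < 2:
            continue
        cs.append(redundancy(net, i) / (k - 1))
    if not cs:
        return _UNDEF, net.order
    return float(np.mean(cs)), net.order - len(cs)


def shortest_path_feature(net: BehaviorNetwork) -> tuple[float, int]:
    """Mean shortest-path length l over unordered reachable pairs.

    Returns ``(l, n_unreachable_pairs)``; undefined when no pair is reachable.
    """
    n = net.order
    if n < 2:
        return _UNDEF, 0
    D, _ = _distances_and_sigma(net.adjacency)
    iu = np.triu_indices(n, 1)
    d = D[iu]
    reach = np.isfinite(d)
    if not reach.any():
        return _UNDEF, int((~reach).sum())
    return float(d[reach].mean()), int((~reach).sum())


def betweenness_feature(net: BehaviorNetwork, indicator: bool = False) -> float:
    """Mean unnormalized betweenness centrality x over nodes.

    x_i sums sigma_st(i)/g_st over ordered pairs s != t with both distinct
    from i; unreachable pairs contribute 0. With ``indicator=True`` the
    fractional count sigma_st(i) is replaced by the 0/1 indicator of whether
    i lies on *any* shortest s-t path (the two coincide when shortest paths
    are unique).
    """
    n = net.order
    if n == 0:
        return _UNDEF
    if n < 3:
        return 0.0
    D, S = _distances_and_sigma(net.adjacency)
    x = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t or np.isinf(D[s, t]):
                continue
            g_st = S[s, t]
            for i in range(n):
                if i == s or i == t:
                    continue
                if D[s, i] + D[i, t] == D[s, t]:
                    if indicator:
                        x[i] += 1.0 / g_st
                    else:
                        x[i] += S[s, i] * S[i, t] / g_st
    return float(x.mean())


def closeness_feature(net: BehaviorNetwork) -> float:
    """Mean over nodes of cl_i = 1 / sum_j d_ij (reachable j only).

    Isolated nodes (reaching nothing) are excluded from the mean; undefined
    when every node is isolated.
    """
    n = net.order
    if n < 2:
        return _UNDEF
    D, _ = _distances_and_sigma(net.adjacency)
    cls = []
    for i in range(n):
        d = D[i]
        mask = np.isfinite(d) & (np.arange(n) != i)
        total = d[mask].sum()
        if mask.any() and total > 0:
            cls.append(1.0 / total)
    if not cls:
        return _UNDEF
    return float(np.mean(cls))


def feature_vector(net: BehaviorNetwork, n_stops: float | None = None) -> NetworkFeatures:
    """Assemble all eight features of a network with defined flags.

    ``n_stops`` is the stop count for dynamic networks; for static or global
    networks pass None and the feature is flagged undefined.
    """
    n = net.order
    clustering, _ = clustering_ws(net) if n else (_UNDEF, 0)
    l, n_unreach = shortest_path_feature(net) if n else (_UNDEF, 0)
    feats = NetworkFeatures(
        n_stops=float(n_stops) if n_stops is not None else _UNDEF,
        order=n,
        degree=degree_feature(net),
        density=density(net),
        clustering=clustering,
        shortest_path=l,
        betweenness=betweenness_feature(net) if n else _UNDEF,
        closeness=closeness_feature(net) if n else _UNDEF,
        mean_degree=(2.0 * net.n_links / n) if n else _UNDEF,
        n_unreachable_pairs=n_unreach,
    )
    feats.defined = {k: not (isinstance(v, float) and math.isnan(v))
                     for k, v in feats.as_dict().items()}
    return feats
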