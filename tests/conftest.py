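import numpy as np
import pytest

from maznet.arena import ArenaSpec
from maznet.network import BehaviorNetwork
from maznet.trajectory import Trajectory


@pytest.fixture(scope="session")
def spec() -> ArenaSpec:
    return ArenaSpec()


@pytest.fixture(scope="session")
def layout(spec):
    from maznet.static import default_static_layout

    return default_static_layout(spec)


def make_network(adj: np.ndarray, xy: np.ndarray | None = None) -> BehaviorNetwork:
    """BehaviorNetwork from a binary adjacency (counts = adjacency)."""
    adj = np.asarray(adj, dtype=int)
    n = len(adj)
    if xy is None:
        xy = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return BehaviorNetwork(node_xy=xy, adjacency=adj, transition_counts=adj.copy())


def random_graph(rng: np.random.Generator, n: int, p: float = 0.5) -> BehaviorNetwork:
    """Erdos-Renyi behavioral network on n nodes."""
    upper = rng.random((n, n)) < p
    A = np.triu(upper, 1).astype(int)
    A = A + A.T
    return make_network(A)


def random_trajectory(rng: np.random.Generator, spec: ArenaSpec, n_frames: int = 100,
                      step_sd: float = 30.0) -> Trajectory:
    """Seeded random walk confined to the arena (no behavioral structure)."""
    c = np.asarray(spec.center)
    pos = c + rng.normal(0, 40, 2)
    pts = [pos.copy()]
    for _ in range(n_frames - 1):
        pos = pos + rng.normal(0, step_sd, 2)
        r = np.linalg.norm(pos - c)
        if r > spec.arena_radius:
            pos = c + (pos - c) * (spec.arena_radius / r)
        pts.append(pos.copy())
    xy = np.asarray(pts)
    return Trajectory(t=np.arange(n_frames) / spec.frame_rate, xy=xy)
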