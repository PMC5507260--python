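import numpy as np
import pytest

from maznet.dynamic import StopEpisode, build_local_network, cca_cluster, detect_stops
from maznet.trajectory import Trajectory

from conftest import random_trajectory


def _traj(xy):
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    return Trajectory(t=np.arange(len(xy)) / 5.0, xy=xy)


def brute_force_stops(traj, spec):
    """Sliding-window + run-merge oracle."""
    xy = traj.xy
    w = spec.stop_window
    n = len(xy)
    if n < w:
        return []
    qualifying = []
    for i in range(n - w + 1):
        path = sum(float(np.linalg.norm(xy[i + k + 1] - xy[i + k]))
                   for k in range(w - 1))
        if path < spec.stop_threshold:
            qualifying.append(i)
    # merge windows that share frames into maximal non-overlapping episodes
    episodes = []
    run = []
    for i in qualifying:
        if run and i > run[-1] + w - 1:
            start, end = run[0], run[-1] + w - 1
            episodes.append((start, end, tuple(xy[start:end + 1].mean(axis=0))))
            run = []
        run.append(i)
    if run:
        start, end = run[0], run[-1] + w - 1
        episodes.append((start, end, tuple(xy[start:end + 1].mean(axis=0))))
    return episodes


class TestDetectStops:
    def test_stationary_trace_single_episode(self, spec):
        p = np.array(spec.center)
        stops = detect_stops(_traj(np.tile(p, (20, 1))), spec)
        assert len(stops) == 1
        assert stops[0].start_frame == 0 and stops[0].end_frame == 19
        np.testing.assert_allclose(stops[0].centroid, p)

    def test_constant_motion_no_episode(self, spec):
        xy = np.column_stack([100 + 10.0 * np.arange(30), np.full(30, 250.0)])
        assert detect_stops(_traj(xy), spec) == []

    def test_short_trajectory_empty(self, spec):
        assert detect_stops(_traj([[0, 0], [1, 1]]), spec) == []

    def test_two_pauses_recovered(self, spec):
        rng = np.random.default_rng(31)
        a, b = np.array([150.0, 150.0]), np.array([350.0, 350.0])
        seg1 = a + rng.normal(0, 1.5, (10, 2))
        transit = np.linspace(a, b, 12)
        seg2 = b + rng.normal(0, 1.5, (10, 2))
        traj = _traj(np.vstack([seg1, transit, seg2]))
        stops = detect_stops(traj, spec)
        assert len(stops) == 2
        assert np.linalg.norm(np.array(stops[0].centroid) - a) < 10
        assert np.linalg.norm(np.array(stops[1].centroid) - b) < 10

    def test_matches_brute_force_oracle(self, spec):
        rng = np.random.default_rng(32)
        for _ in range(30):
            # mix of slow and fast segments to exercise the threshold
            traj = random_trajectory(rng, spec, n_frames=100,
                                     step_sd=float(rng.uniform(1, 15)))
            got = [(s.start_frame, s.end_frame, s.centroid)
                   for s in detect_stops(traj, spec)]
            expected = brute_force_stops(traj, spec)
            assert [(g[0], g[1]) for g in got] == [(e[0], e[1]) for e in expected]
            for g, e in zip(got, expected):
                np.testing.assert_allclose(g[2], e[2], atol=1e-9)

    def test_translation_and_rotation_invariance(self, spec):
        rng = np.random.default_rng(33)
        traj = random_trajectory(rng, spec, n_frames=80, step_sd=4.0)
        base = [(s.start_frame, s.end_frame) for s in detect_stops(traj, spec)]
        shifted = traj.with_xy(traj.xy + np.array([13.0, -7.0]))
        assert [(s.start_frame, s.end_frame) for s in detect_stops(shifted, spec)] == base
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = traj.with_xy((traj.xy - spec.center) @ R.T + spec.center)
        assert [(s.start_frame, s.end_frame) for s in detect_stops(rotated, spec)] == base


class TestCCACluster:
    def test_two_separated_groups(self):
        rng = np.random.default_rng(34)
        g1 = np.array([100.0, 100.0]) + rng.uniform(-2, 2, (10, 2))
        g2 = np.array([200.0, 100.0]) + rng.uniform(-2, 2, (10, 2))
        pts = np.vstack([g1, g2])
        cents, labels, converged = cca_cluster(pts, 20.0)
        assert converged
        assert len(cents) == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        got = {tuple(np.round(c, 6)) for c in cents}
        expected = {tuple(np.round(g1.mean(axis=0), 6)), tuple(np.round(g2.mean(axis=0), 6))}
        assert got == expected

    def test_single_point(self):
        cents, labels, _ = cca_cluster(np.array([[5.0, 7.0]]), 20.0)
        assert len(cents) == 1
        np.testing.assert_allclose(cents[0], [5.0, 7.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cca_cluster(np.empty((0, 2)), 20.0)

    def test_every_point_assigned_and_centroids_are_member_means(self):
        rng = np.random.default_rng(35)
        pts = rng.uniform(0, 500, (200, 2))
        cents, labels, _ = cca_cluster(pts, 20.0)
        assert len(labels) == 200
        assert set(labels) == set(range(len(cents)))
        for k in range(len(cents)):
            np.testing.assert_allclose(cents[k], pts[labels == k].mean(axis=0), atol=1e-9)

    def test_order_permutation_stable_on_separated_data(self):
        # inter-cluster gaps > 3x threshold: partition must not depend on order
        rng = np.random.default_rng(36)
        centers = np.array([[100, 100], [250, 100], [100, 250], [300, 300]], dtype=float)
        # within-cluster diameter below the threshold so each cluster is one node
        pts = np.vstack([c + rng.uniform(-5, 5, (15, 2)) for c in centers])
        _, base_labels, _ = cca_cluster(pts, 20.0)

        def partition(labels):
            groups = {}
            for i, l in enumerate(labels):
                groups.setdefault(l, set()).add(i)
            return {frozenset(g) for g in groups.values()}

        base = partition(base_labels)
        for _ in range(5):
            perm = rng.permutation(len(pts))
            _, labels_p, _ = cca_cluster(pts[perm], 20.0)
            # map back to original indices
            unperm = np.empty_like(labels_p)
            unperm[perm] = labels_p
            assert partition(unperm) == base


class TestBuildLocalNetwork:
    def _stops(self, coords):
        return [StopEpisode(5 * i, 5 * i + 4, tuple(c)) for i, c in enumerate(coords)]

    def test_all_nearby_stops_one_node_no_links(self, spec):
        net = build_local_network(self._stops([[100, 100], [103, 100], [100, 104]]), spec)
        assert net.order == 1
        assert net.n_links == 0

    def test_alternating_two_nodes_one_link_count_three(self, spec):
        net = build_local_network(self._stops([[100, 100], [300, 300],
                                               [100, 100], [300, 300]]), spec)
        assert net.order == 2
        assert net.n_links == 1
        assert net.transition_counts.max() == 3

    def test_empty_stops_empty_network(self, spec):
        net = build_local_network([], spec)
        assert net.order == 0

    def test_adjacency_matches_transition_tabulation(self, spec):
        rng = np.random.default_rng(37)
        from maznet.dynamic import cca_cluster as cca

        for _ in range(20):
            coords = rng.uniform(50, 450, (rng.integers(2, 30), 2))
            stops = self._stops(coords)
            net = build_local_network(stops, spec)
            _, labels, _ = cca(coords, spec.cca_threshold)
            n = net.order
            A = np.zeros((n, n), dtype=int)
            for u, v in zip(labels[:-1], labels[1:]):
                if u != v:
                    A[u, v] = A[v, u] = 1
            np.testing.assert_array_equal(net.adjacency, A)
            assert np.all(np.diag(net.adjacency) == 0)
            assert net.n_links == int(A.sum() // 2)
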