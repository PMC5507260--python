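import itertools

import networkx as nx
import numpy as np
import pytest

from maznet.metrics import (
    betweenness_feature,
    closeness_feature,
    clustering_ws,
    degree_feature,
    density,
    feature_vector,
    link_count,
    redundancy,
    shortest_path_feature,
)

from conftest import make_network, random_graph


def _adj(edges, n):
    A = np.zeros((n, n), dtype=int)
    for i, j in edges:
        A[i, j] = A[j, i] = 1
    return A


TRIANGLE = make_network(_adj([(0, 1), (1, 2), (0, 2)], 3))
PATH3 = make_network(_adj([(0, 1), (1, 2)], 3))
PATH4 = make_network(_adj([(0, 1), (1, 2), (2, 3)], 4))
STAR4 = make_network(_adj([(0, 1), (0, 2), (0, 3)], 4))
EMPTY4 = make_network(np.zeros((4, 4), dtype=int))
PAIR = make_network(_adj([(0, 1)], 2))


def brute_betweenness(net):
    """Exhaustive enumeration of all shortest paths (oracle, n <= 8)."""
    g = net.to_networkx()
    n = net.order
    x = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        if not nx.has_path(g, s, t):
            continue
        paths = list(nx.all_shortest_paths(g, s, t))
        for i in range(n):
            if i in (s, t):
                continue
            through = sum(1 for p in paths if i in p)
            x[i] += through / len(paths)
    return x.mean()


class TestClosedForms:
    def test_triangle(self):
        assert link_count(TRIANGLE) == 3
        assert degree_feature(TRIANGLE) == pytest.approx(1.0)
        assert density(TRIANGLE) == pytest.approx(1.0)
        assert clustering_ws(TRIANGLE)[0] == pytest.approx(1.0)
        assert shortest_path_feature(TRIANGLE)[0] == pytest.approx(1.0)
        assert betweenness_feature(TRIANGLE) == pytest.approx(0.0)
        assert closeness_feature(TRIANGLE) == pytest.approx(0.5)

    def test_path3(self):
        # l over pairs (1,1,2); x_b = 2 ordered pairs; cl = (1/2 + 1/3 + 1/3)/3
        assert shortest_path_feature(PATH3)[0] == pytest.approx(4 / 3)
        assert betweenness_feature(PATH3) == pytest.approx(2 / 3)
        assert closeness_feature(PATH3) == pytest.approx(7 / 18)

    def test_path4_density(self):
        assert density(PATH4) == pytest.approx(0.5)

    def test_star_clustering_zero(self):
        # center has no neighbor-neighbor links; leaves (degree 1) excluded
        assert clustering_ws(STAR4)[0] == pytest.approx(0.0)
        assert clustering_ws(STAR4)[1] == 3

    def test_empty_graph(self):
        assert link_count(EMPTY4) == 0
        assert degree_feature(EMPTY4) == 0.0
        assert np.isnan(clustering_ws(EMPTY4)[0])
        assert np.isnan(shortest_path_feature(EMPTY4)[0])
        assert np.isnan(closeness_feature(EMPTY4))

    def test_two_linked_nodes_closeness(self):
        assert closeness_feature(PAIR) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", range(3, 9))
    def test_complete_graph_identities(self, n):
        net = make_network(1 - np.eye(n, dtype=int))
        assert density(net) == pytest.approx(1.0)
        assert clustering_ws(net)[0] == pytest.approx(1.0)
        assert shortest_path_feature(net)[0] == pytest.approx(1.0)
        assert betweenness_feature(net) == pytest.approx(0.0)

    @pytest.mark.parametrize("n", range(4, 9))
    def test_ring_graph(self, n):
        net = make_network(_adj([(i, (i + 1) % n) for i in range(n)], n))
        assert density(net) == pytest.approx(2 / (n - 1))
        # ring of n >= 5 has no triangles
        expected_c = 1.0 if n == 3 else 0.0
        if n >= 4:
            assert clustering_ws(net)[0] == pytest.approx(expected_c if n != 4 else 0.0)
        g = nx.cycle_graph(n)
        assert shortest_path_feature(net)[0] == pytest.approx(
            nx.average_shortest_path_length(g))


class TestRandomGraphOracles:
    def test_degree_is_half_conventional_mean_degree(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            net = random_graph(rng, int(rng.integers(2, 9)))
            g = net.to_networkx()
            mean_deg = np.mean([d for _, d in g.degree()])
            assert degree_feature(net) == pytest.approx(mean_deg / 2)
            assert link_count(net) == g.number_of_edges()

    def test_density_matches_pair_count(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            net = random_graph(rng, n)
            assert density(net) == pytest.approx(net.n_links / (n * (n - 1) / 2))

    def test_redundancy_triangle_identity(self):
        # C_i = R_i/(k_i-1) == 2 T_i / (k_i (k_i - 1)) node by node
        rng = np.random.default_rng(43)
        for _ in range(100):
            net = random_graph(rng, int(rng.integers(3, 9)))
            g = net.to_networkx()
            tri = nx.triangles(g)
            for i in range(net.order):
                k = int(net.adjacency[i].sum())
                if k < 2:
                    continue
                c_red = redundancy(net, i) / (k - 1)
                c_tri = 2 * tri[i] / (k * (k - 1))
                assert c_red == pytest.approx(c_tri, abs=1e-12)

    def test_clustering_matches_networkx_on_qualifying_nodes(self):
        rng = np.random.default_rng(44)
        for _ in range(50):
            net = random_graph(rng, int(rng.integers(3, 9)))
            got, _ = clustering_ws(net)
            g = net.to_networkx()
            cs = [c for i, c in nx.clustering(g).items() if g.degree(i) >= 2]
            if not cs:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(np.mean(cs), abs=1e-12)

    def test_shortest_path_matches_bfs_oracle(self):
        rng = np.random.default_rng(45)
        for _ in range(50):
            net = random_graph(rng, int(rng.integers(2, 9)))
            got, n_unreach = shortest_path_feature(net)
            g = net.to_networkx()
            lengths = []
            unreach = 0
            for s, t in itertools.combinations(range(net.order), 2):
                try:
                    lengths.append(nx.shortest_path_length(g, s, t))
                except nx.NetworkXNoPath:
                    unreach += 1
            assert n_unreach == unreach
            if lengths:
                assert got == pytest.approx(np.mean(lengths))
            else:
                assert np.isnan(got)

    def test_betweenness_matches_enumeration_and_networkx(self):
        rng = np.random.default_rng(46)
        for _ in range(30):
            net = random_graph(rng, int(rng.integers(3, 9)))
            got = betweenness_feature(net)
            assert got == pytest.approx(brute_betweenness(net), abs=1e-12)
            g = net.to_networkx()
            # networkx counts unordered pairs; the ordered-pair sum is twice that
            bc = nx.betweenness_centrality(g, normalized=False)
            assert got == pytest.approx(2 * np.mean(list(bc.values())), abs=1e-9)

    def test_closeness_matches_distance_sums(self):
        rng = np.random.default_rng(47)
        for _ in range(50):
            net = random_graph(rng, int(rng.integers(2, 9)))
            got = closeness_feature(net)
            g = net.to_networkx()
            vals = []
            for i in range(net.order):
                dists = nx.single_source_shortest_path_length(g, i)
                total = sum(d for j, d in dists.items() if j != i)
                if total > 0:
                    vals.append(1.0 / total)
            if vals:
                assert got == pytest.approx(np.mean(vals), abs=1e-12)
            else:
                assert np.isnan(got)


class TestProperties:
    def test_adding_link_never_increases_shortest_path(self):
        rng = np.random.default_rng(48)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            net = random_graph(rng, n, p=0.4)
            missing = [(i, j) for i, j in itertools.combinations(range(n), 2)
                       if net.adjacency[i, j] == 0]
            if not missing or net.n_links == 0:
                continue
            l0, u0 = shortest_path_feature(net)
            i, j = missing[rng.integers(len(missing))]
            A = net.adjacency.copy()
            A[i, j] = A[j, i] = 1
            l1, u1 = shortest_path_feature(make_network(A))
            if u0 == u1 == 0:  # comparable only when both fully connected
                assert l1 <= l0 + 1e-12

    def test_features_invariant_under_relabeling(self):
        rng = np.random.default_rng(49)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            net = random_graph(rng, n)
            perm = rng.permutation(n)
            A2 = net.adjacency[np.ix_(perm, perm)]
            net2 = make_network(A2)
            for f in (degree_feature, density, betweenness_feature, closeness_feature):
                a, b = f(net), f(net2)
                assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-12)
            a, b = clustering_ws(net)[0], clustering_ws(net2)[0]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b, abs=1e-12)

    def test_indicator_form_coincides_on_unique_path_graphs(self):
        # trees have unique shortest paths: fractional == indicator
        rng = np.random.default_rng(50)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
            from maznet.network import BehaviorNetwork

            net = BehaviorNetwork.from_networkx(g)
            assert betweenness_feature(net) == pytest.approx(
                betweenness_feature(net, indicator=True), abs=1e-12)


class TestFeatureVector:
    def test_triangle_assembly(self):
        fv = feature_vector(TRIANGLE, n_stops=5)
        assert fv.n_stops == 5
        assert fv.order == 3
        assert fv.degree == pytest.approx(1.0)
        assert fv.density == pytest.approx(1.0)
        assert fv.clustering == pytest.approx(1.0)
        assert fv.shortest_path == pytest.approx(1.0)
        assert fv.betweenness == pytest.approx(0.0)
        assert fv.closeness == pytest.approx(0.5)
        assert all(fv.defined[k] for k in fv.FEATURES)

    def test_empty_network_all_undefined(self):
        from maznet.network import empty_network

        fv = feature_vector(empty_network("dynamic"), n_stops=0)
        assert fv.order == 0
        for k in ("degree", "density", "clustering", "shortest_path",
                  "betweenness", "closeness"):
            assert not fv.defined[k]
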