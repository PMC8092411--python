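"""Markov Stability: objective, optimizer, VI, scan and robust selection."""

import numpy as np
import networkx as nx
import networkx.algorithms.community as nxcom
import pytest

from stressrec import stability
from stressrec.stability import Partition


def weighted(graph, w=1.0):
    for e in graph.edges:
        graph.edges[e].setdefault("weight", w)
    return graph


def random_connected_graph(rng, n, p=0.5, wmin=0.1, wmax=2.0):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < p:
                g.add_edge(a, b, weight=float(rng.uniform(wmin, wmax)))
    comps = list(nx.connected_components(g))
    for c1, c2 in zip(comps, comps[1:]):
        g.add_edge(next(iter(c1)), next(iter(c2)), weight=wmin)
    return g


def two_cliques_bridged():
    """Two triangles joined by a floor-weight bridge: one clear optimum."""
    g = nx.Graph()
    for offset in (0, 3):
        for a in range(3):
            for b in range(a + 1, 3):
                g.add_edge(offset + a, offset + b, weight=1.0)
    g.add_edge(2, 3, weight=1e-6)
    return g


class TestStationaryDistribution:
    def test_single_edge(self):
        g = weighted(nx.path_graph(2))
        np.testing.assert_allclose(stability.stationary_distribution(g), [0.5, 0.5])

    def test_star(self):
        g = weighted(nx.star_graph(3))
        pi = stability.stationary_distribution(g)
        np.testing.assert_allclose(pi, [0.5, 1 / 6, 1 / 6, 1 / 6])
        assert pi.sum() == pytest.approx(1.0)

    def test_disconnected_raises(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_node(2)
        with pytest.raises(ValueError):
            stability.stationary_distribution(g)


class TestPartitionStability:
    @pytest.mark.parametrize("t", [0.0, 0.5, 1.0, 5.0])
    @pytest.mark.parametrize("mode", ["exact", "linearized"])
    def test_all_in_one_partition_scores_zero(self, t, mode):
        g = random_connected_graph(np.random.default_rng(0), 8)
        labels = np.zeros(8, dtype=int)
        assert stability.partition_stability(g, labels, t, mode=mode) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_two_node_singletons_at_time_zero(self):
        g = weighted(nx.path_graph(2))
        r = stability.partition_stability(g, np.array([0, 1]), 0.0, mode="exact")
        assert r == pytest.approx(0.5)

    def test_triangle_barbell_linearized_at_unit_time_is_modularity(self):
        g = nx.Graph()
        for offset in (0, 3):
            for a in range(3):
                for b in range(a + 1, 3):
                    g.add_edge(offset + a, offset + b, weight=1.0)
        g.add_edge(2, 3, weight=1.0)
        labels = np.array([0, 0, 0, 1, 1, 1])
        r = stability.partition_stability(g, labels, 1.0, mode="linearized")
        assert r == pytest.approx(2 * (3 / 7 - (7 / 14) ** 2))
        assert r == pytest.approx(0.357142857, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_linearized_unit_time_equals_newman_modularity(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, int(rng.integers(6, 30)), p=0.3)
        labels = rng.integers(0, 4, g.number_of_nodes())
        communities = [
            set(np.flatnonzero(labels == c)) for c in np.unique(labels)
        ]
        q = nxcom.modularity(g, communities, weight="weight")
        r = stability.partition_stability(g, labels, 1.0, mode="linearized")
        assert r == pytest.approx(q, abs=1e-12)

    def test_exact_and_linearized_agree_to_first_order(self):
        g = weighted(nx.karate_club_graph())
        labels = np.arange(34) % 4
        gaps = []
        for t in (1e-3, 1e-2):
            re = stability.partition_stability(g, labels, t, mode="exact")
            rl = stability.partition_stability(g, labels, t, mode="linearized")
            gaps.append(abs(re - rl))
        # second-order vanishing: the gap scales like t^2
        assert gaps[0] < 1e-5 and gaps[1] < 1e-3
        assert gaps[1] / gaps[0] == pytest.approx(100, rel=0.2)

    def test_invalid_mode_and_size_cap(self):
        g = weighted(nx.path_graph(3))
        with pytest.raises(ValueError):
            stability.partition_stability(g, np.zeros(3, int), 1.0, mode="bogus")
        with pytest.raises(ValueError):
            stability.partition_stability(
                g, np.zeros(3, int), 1.0, mode="exact", n_exact=2
            )


class TestOptimizer:
    def test_recovers_planted_cliques(self):
        g = two_cliques_bridged()
        part = stability.optimize_partition(g, t=1.0, n_restarts=5, seed=0)
        assert part.n_clusters == 2
        assert len({part.labels[i] for i in (0, 1, 2)}) == 1
        assert len({part.labels[i] for i in (3, 4, 5)}) == 1

    def test_more_restarts_never_hurt(self):
        g = random_connected_graph(np.random.default_rng(7), 15, p=0.3)
        r1 = stability.partition_stability(
            g, stability.optimize_partition(g, 1.0, n_restarts=1, seed=3), 1.0
        )
        r50 = stability.partition_stability(
            g, stability.optimize_partition(g, 1.0, n_restarts=50, seed=3), 1.0
        )
        assert r50 >= r1 - 1e-12

    def test_deterministic_per_seed(self):
        g = random_connected_graph(np.random.default_rng(8), 20, p=0.3)
        p1 = stability.optimize_partition(g, 0.7, n_restarts=8, seed=5)
        p2 = stability.optimize_partition(g, 0.7, n_restarts=8, seed=5)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    @pytest.mark.parametrize("seed", range(10))
    def test_attains_brute_force_optimum_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = random_connected_graph(rng, int(rng.integers(4, 9)))
        for t in (0.5, 1.0, 2.0):
            best = stability.brute_force_optimum(g, t)
            opt = stability.optimize_partition(g, t, n_restarts=20, seed=seed)
            assert stability.partition_stability(
                g, opt, t
            ) >= stability.partition_stability(g, best, t) - 1e-12


class TestVariationOfInformation:
    def test_identity_and_symmetry(self):
        nodes = list(range(6))
        p = Partition(nodes, np.array([0, 0, 1, 1, 2, 2]))
        q = Partition(nodes, np.array([0, 1, 1, 1, 2, 0]))
        assert stability.variation_of_information(p, p) == 0.0
        assert stability.variation_of_information(
            p, q
        ) == pytest.approx(stability.variation_of_information(q, p))

    def test_singletons_vs_lump(self):
        nodes = list(range(4))
        p = Partition(nodes, np.arange(4))
        q = Partition(nodes, np.zeros(4, int))
        assert stability.variation_of_information(p, q) == pytest.approx(np.log(4))

    def test_mismatched_nodes_raise(self):
        p = Partition([0, 1], np.array([0, 1]))
        q = Partition([0, 2], np.array([0, 1]))
        with pytest.raises(ValueError):
            stability.variation_of_information(p, q)


class TestScanAndSelection:
    def test_small_scan_has_finite_stability(self):
        g = two_cliques_bridged()
        scan = stability.scan_markov_times(
            g, t_grid=np.array([0.1, 1.0, 10.0]), n_restarts=3, seed=0
        )
        assert np.isfinite(scan.stability).all()
        assert len(scan.partitions) == 3
        assert len(scan.consecutive_vi) == 2

    def test_cluster_count_coarsens_with_markov_time(self):
        import pandas as pd

        from stressrec.matrices import TemporalProfileMatrix
        from stressrec.network import similarity_graph

        rng = np.random.default_rng(0)
        blocks = [
            rng.normal(0, 2, 7) + rng.normal(0, 0.1, (8, 7)) for _ in range(3)
        ]
        arr = np.vstack(blocks)
        z = (arr - arr.mean(axis=1, keepdims=True)) / arr.std(axis=1, keepdims=True)
        profiles = TemporalProfileMatrix(
            profiles=pd.DataFrame(
                z, index=[f"F{i}" for i in range(24)], columns=range(7)
            )
        )
        g = similarity_graph(profiles, k=3)
        scan = stability.scan_markov_times(
            g, t_grid=np.logspace(-2, 2, 12), n_restarts=5, seed=0
        )
        increases = int((np.diff(scan.n_clusters) > 0).sum())
        assert increases <= 1

    def test_unambiguous_graph_has_zero_restart_vi(self):
        g = two_cliques_bridged()
        scan = stability.scan_markov_times(
            g, t_grid=np.array([1.0]), n_restarts=6, seed=1
        )
        assert scan.mean_restart_vi[0] == pytest.approx(0.0)
        assert scan.n_clusters[0] == 2

    def _fake_scan(self, t_grid, n_clusters, vis, n_nodes=40):
        parts = []
        rng = np.random.default_rng(0)
        for c in n_clusters:
            labels = np.arange(n_nodes) % c
            parts.append(Partition(list(range(n_nodes)), labels))
        return stability.StabilityScan(
            t_grid=np.asarray(t_grid, float),
            partitions=parts,
            stability=np.linspace(1, 0.1, len(t_grid)),
            n_clusters=np.asarray(n_clusters),
            mean_restart_vi=np.asarray(vis, float),
            consecutive_vi=np.zeros(len(t_grid) - 1),
        )

    def test_single_plateau_selected(self):
        scan = self._fake_scan(
            [0.1, 0.3, 1.0, 3.0, 10.0], [5, 2, 2, 2, 1], [0.5, 0.0, 0.0, 0.0, 0.0]
        )
        part, info = stability.select_robust_partition(scan)
        assert part.n_clusters == 2 and not info["fallback"]

    def test_equal_plateaus_tie_toward_larger_t(self):
        scan = self._fake_scan(
            [0.1, 0.3, 1.0, 3.0], [4, 4, 2, 2], [0.0, 0.0, 0.0, 0.0]
        )
        part, info = stability.select_robust_partition(scan)
        assert part.n_clusters == 2

    def test_no_plateau_falls_back_to_max_stability(self):
        scan = self._fake_scan([0.1, 1.0, 10.0], [5, 3, 2], [0.9, 0.9, 0.9])
        part, info = stability.select_robust_partition(scan, vi_max=0.01)
        assert info["fallback"]
        assert part.n_clusters == 5  # stability is highest at the first point


class TestBruteForce:
    def test_triangle_prefers_all_in_one_at_unit_time(self):
        g = weighted(nx.complete_graph(3))
        part = stability.brute_force_optimum(g, 1.0)
        assert part.n_clusters == 1

    def test_two_cliques_recovered(self):
        part = stability.brute_force_optimum(two_cliques_bridged(), 1.0)
        assert part.n_clusters == 2

    def test_single_node(self):
        g = nx.Graph()
        g.add_edge(0, 0, weight=1.0)
        part = stability.brute_force_optimum(g, 1.0)
        assert part.n_clusters == 1

    def test_size_cap(self):
        g = weighted(nx.path_graph(11))
        with pytest.raises(ValueError):
            stability.brute_force_optimum(g, 1.0)


class TestClusterMeans:
    def test_singleton_clusters_reproduce_profiles(self):
        import pandas as pd

        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [0.0, -1.0, 1.0]], index=["A", "B"], columns=[0, 1, 2]
        )
        part = Partition(["A", "B"], np.array([0, 1]))
        means = stability.cluster_mean_profiles(part, profiles)
        np.testing.assert_allclose(means.loc[0, ["mean_0", "mean_1", "mean_2"]], [1, 2, 3])
        assert means.loc[0, "size"] == 1

    def test_duplicate_members_have_zero_se(self):
        import pandas as pd

        profiles = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]], index=["A", "B"], columns=[0, 1, 2]
        )
        part = Partition(["A", "B"], np.array([0, 0]))
        means = stability.cluster_mean_profiles(part, profiles)
        np.testing.assert_allclose(means.loc[0, ["se_0", "se_1", "se_2"]], 0.0)
        np.testing.assert_allclose(means.loc[0, ["mean_0", "mean_1", "mean_2"]], [1, 2, 3])

    def test_two_cluster_arithmetic(self):
        import pandas as pd

        profiles = pd.DataFrame(
            [[0.0, 2.0], [2.0, 4.0], [1.0, 1.0], [3.0, 3.0]],
            index=list("ABCD"),
            columns=[0, 1],
        )
        part = Partition(list("ABCD"), np.array([0, 0, 1, 1]))
        means = stability.cluster_mean_profiles(part, profiles)
        np.testing.assert_allclose(means.loc[0, ["mean_0", "mean_1"]], [1.0, 3.0])
        np.testing.assert_allclose(means.loc[1, ["mean_0", "mean_1"]], [2.0, 2.0])
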