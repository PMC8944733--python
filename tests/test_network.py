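import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pepcsn import (
    build_csn,
    descriptor_matrix,
    detect_communities,
    export_graphml,
    minmax_normalize,
    network_metrics,
    read_graphml,
    split_giant_outliers,
    threshold_scan,
)
from pepcsn.descriptors import DescriptorMatrix
from pepcsn.network import SimilarityNetwork

from conftest import random_peptides
from oracles import (
    brute_diameter,
    brute_modularity,
    graph_density,
    local_clustering,
)


def dm(points, ids=None):
    """Normalized descriptor matrix straight from coordinates."""
    ids = ids or [f"n{i}" for i in range(len(points))]
    return DescriptorMatrix(
        pd.DataFrame(points, index=ids, columns=[f"d{j}" for j in range(len(points[0]))]),
        normalized=True,
    )


def wrap(g, t=0.5):
    return SimilarityNetwork(g, t)


class TestBuildCsn:
    def test_threshold_zero_gives_complete_graph(self):
        net = build_csn(dm([(0, 0), (1, 0), (0.3, 0.7), (0.9, 0.2)]), 0.0)
        assert net.n_edges == 6

    def test_threshold_one_connects_only_global_minimum_pairs(self):
        net = build_csn(dm([(0, 0), (0, 0.1), (1, 1)]), 1.0)
        assert net.n_edges == 1
        assert net.graph.has_edge("n0", "n1")

    def test_two_clusters_at_high_threshold(self):
        # hand-computed: close pairs at distance 0.1, far pairs >= ~1.2
        net = build_csn(dm([(0, 0), (0, 0.1), (1, 1), (1, 0.9)]), 0.8)
        assert sorted(tuple(sorted(e)) for e in net.graph.edges) == [
            ("n0", "n1"), ("n2", "n3")
        ]

    def test_all_records_kept_as_nodes(self, synthetic_dataset):
        records, _ = synthetic_dataset
        mat = minmax_normalize(descriptor_matrix(records[:30]))
        net = build_csn(mat, 0.95)
        assert net.n_nodes == 30

    def test_edge_weights_at_least_threshold(self):
        net = build_csn(dm([(0, 0), (0.2, 0.1), (0.5, 0.5), (1, 1)]), 0.4)
        assert all(w >= 0.4 for _, _, w in net.graph.edges.data("weight"))

    def test_fewer_than_two_records_rejected(self):
        with pytest.raises(ValueError):
            build_csn(dm([(0, 0)]), 0.5)


class TestNetworkMetrics:
    def test_complete_graph_k4(self):
        m = network_metrics(wrap(nx.complete_graph(4)))
        assert (m.density, m.average_clustering_coefficient, m.diameter) == (1.0, 1.0, 1)
        assert m.n_triangles == 4

    def test_path_graph(self):
        m = network_metrics(wrap(nx.path_graph(3)))
        assert m.density == pytest.approx(2 / 3)
        assert m.average_clustering_coefficient == 0.0
        assert m.diameter == 2

    def test_average_degree_on_giant_component_scale(self):
        g = nx.gnm_random_graph(528, 4452, seed=0)
        m = network_metrics(wrap(g))
        assert m.average_degree == pytest.approx(16.864, abs=1e-3)

    def test_matches_brute_force_on_small_graph_atlas(self):
        """Density, ACC and diameter agree with first-principles
        recomputation on every graph of <= 6 nodes."""
        for i in range(1, 209):
            g = nx.graph_atlas(i)
            if g.number_of_nodes() == 0:
                continue
            adj = {u: set(g.neighbors(u)) for u in g.nodes}
            m = network_metrics(wrap(g))
            assert m.density == pytest.approx(graph_density(g.nodes, g.edges))
            cc = local_clustering(list(g.nodes), adj)
            assert m.average_clustering_coefficient == pytest.approx(
                np.mean(list(cc.values()))
            )
            if g.number_of_edges() > 0:
                assert m.diameter == brute_diameter(list(g.nodes), adj)


class TestCommunities:
    def test_two_cliques_joined_by_bridge(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        nx.set_edge_attributes(g, 1.0, "weight")
        labels, q = detect_communities(wrap(g), rng_seed=1)
        assert len(set(labels.values())) == 2
        assert q > 0.3
        assert q == pytest.approx(
            brute_modularity(list(g.nodes), list(g.edges), labels)
        )

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(6)
        labels, q = detect_communities(wrap(g), rng_seed=1)
        assert len(set(labels.values())) == 1
        assert q <= 0

    def test_three_disjoint_triangles_modularity_two_thirds(self):
        g = nx.disjoint_union_all([nx.complete_graph(3)] * 3)
        labels, q = detect_communities(wrap(g), rng_seed=1)
        assert len(set(labels.values())) == 3
        assert q == pytest.approx(2 / 3)

    def test_edgeless_network_trivial_partition(self):
        g = nx.empty_graph(4)
        labels, q = detect_communities(wrap(g))
        assert len(set(labels.values())) == 4
        assert q == 0.0

    def test_deterministic_for_fixed_seed(self):
        g = nx.gnm_random_graph(40, 120, seed=3)
        nx.set_edge_attributes(g, 1.0, "weight")
        l1, q1 = detect_communities(wrap(g), rng_seed=42)
        l2, q2 = detect_communities(wrap(g), rng_seed=42)
        assert l1 == l2 and q1 == q2

    def test_beats_trivial_partition_on_disconnected_graph(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        _, q = detect_communities(wrap(g), rng_seed=1)
        trivial = brute_modularity(
            list(g.nodes), list(g.edges), {u: 0 for u in g.nodes}
        )
        assert q >= trivial


class TestSplitGiantOutliers:
    def test_triangle_plus_isolates(self):
        g = nx.complete_graph(3)
        g.add_nodes_from([10, 11])
        sub, outliers = split_giant_outliers(wrap(g))
        assert sorted(outliers) == [10, 11]
        assert sub.n_nodes == 3 and sub.n_edges == 3

    def test_edgeless_graph_all_outliers(self):
        g = nx.empty_graph(5)
        sub, outliers = split_giant_outliers(wrap(g))
        assert sub.n_nodes == 0 and len(outliers) == 5

    def test_partition_covers_all_nodes(self, synthetic_dataset):
        records, _ = synthetic_dataset
        mat = minmax_normalize(descriptor_matrix(records[:40]))
        net = build_csn(mat, 0.8)
        sub, outliers = split_giant_outliers(net)
        assert sub.n_nodes + len(outliers) == net.n_nodes


class TestThresholdScan:
    def test_seventeen_thresholds_give_seventeen_rows(self, synthetic_dataset):
        records, _ = synthetic_dataset
        mat = minmax_normalize(descriptor_matrix(records[:25]))
        ts = np.round(np.arange(0.10, 0.901, 0.05), 2).tolist()
        table = threshold_scan(mat, ts)
        assert len(table) == 17

    def test_edges_and_density_anti_monotone(self, synthetic_dataset):
        records, _ = synthetic_dataset
        mat = minmax_normalize(descriptor_matrix(records[:25]))
        table = threshold_scan(mat, [0.1, 0.3, 0.5, 0.7, 0.9])
        assert (np.diff(table["n_edges"]) <= 0).all()
        assert (np.diff(table["density"]) <= 1e-12).all()

    def test_single_threshold_equals_direct_metrics(self):
        mat = dm([(0, 0), (0.5, 0.5), (1, 1), (0.2, 0.9)])
        row = threshold_scan(mat, [0.6]).iloc[0]
        direct = network_metrics(build_csn(mat, 0.6))
        assert row["n_edges"] == direct.n_edges
        assert row["density"] == pytest.approx(direct.density)


class TestGraphML:
    def test_round_trip_nodes_edges_weights(self, tmp_path):
        net = build_csn(dm([(0, 0), (0.1, 0), (1, 1), (0.9, 1)]), 0.5)
        detect_communities(net, rng_seed=1)
        path = export_graphml(net, tmp_path / "net.graphml")
        back = read_graphml(path)
        assert set(back.graph.nodes) == set(net.graph.nodes)
        assert {tuple(sorted(e)) for e in back.graph.edges} == {
            tuple(sorted(e)) for e in net.graph.edges
        }
        assert back.threshold == net.threshold
        assert back.communities == net.communities
        for u, v, w in net.graph.edges.data("weight"):
            assert back.graph[u][v]["weight"] == pytest.approx(w)

    def test_no_community_attribute_when_absent(self, tmp_path):
        net = build_csn(dm([(0, 0), (0.1, 0), (1, 1)]), 0.5)
        path = export_graphml(net, tmp_path / "net.graphml")
        assert read_graphml(path).communities is None
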