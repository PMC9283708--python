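"""Contact-network construction and measures, cross-checked against
brute-force triple enumeration, union-find, and networkx."""

import numpy as np
import pytest

from tumornet import (
    CellConfiguration,
    average_degree,
    build_contact_network,
    clustering,
    connected_components,
    degree_distribution,
    nearest_neighbor_degree,
    summarize,
    transitivity,
    fixture_hardcore_gas,
    fixture_hexagonal,
)
from tumornet.contact_network import EmptyNetworkError
from oracles import (
    brute_adjacency,
    brute_clustering,
    brute_knn,
    brute_transitivity,
    unionfind_components,
)


class TestBuild:
    def test_lone_cell_is_isolated(self):
        net = build_contact_network(np.zeros((1, 2)))
        assert net.n_nodes == 0
        assert net.n_isolated == 1

    def test_contact_triangle(self, triangle):
        net = build_contact_network(triangle)
        assert net.n_nodes == 3
        assert net.n_links == 3
        assert np.all(net.degrees == 2)

    def test_threshold_is_inclusive_at_exactly_one(self):
        pos = np.array([[0.0, 0.0], [1.0, 0.0]])
        net = build_contact_network(pos)
        assert net.n_links == 1
        far = np.array([[0.0, 0.0], [1.001, 0.0]])
        assert build_contact_network(far).n_links == 0

    def test_isolated_cells_counted_but_excluded(self, triangle):
        pos = np.vstack([triangle.positions, [[50.0, 50.0]]])
        net = build_contact_network(pos)
        assert net.n_nodes == 3
        assert net.n_isolated == 1
        assert 3 not in set(net.node_ids)


class TestHexPatchValues:
    """Hand-derived values for the 7-cell kissing configuration."""

    def test_degrees(self, hex_net):
        assert sorted(hex_net.degrees) == [3, 3, 3, 3, 3, 3, 6]

    def test_degree_distribution(self, hex_net):
        pk = degree_distribution(hex_net)
        assert pk == {3: pytest.approx(6 / 7), 6: pytest.approx(1 / 7)}

    def test_average_degree(self, hex_net):
        assert average_degree(hex_net) == pytest.approx(24 / 7)
        assert average_degree(hex_net) == pytest.approx(2 * hex_net.n_links / 7)

    def test_nearest_neighbor_degree(self, hex_net):
        assert nearest_neighbor_degree(hex_net) == pytest.approx(27 / 7)

    def test_transitivity(self, hex_net):
        assert transitivity(hex_net) == pytest.approx(6 / 11)

    def test_clustering(self, hex_net, hex_patch):
        ci, mean_c = clustering(hex_net)
        center = int(hex_patch.ids[np.argmin(np.hypot(*hex_patch.positions.T))])
        assert ci[center] == pytest.approx(0.4)
        ring = [v for k, v in ci.items() if k != center]
        assert ring == pytest.approx([2 / 3] * 6)
        assert mean_c == pytest.approx(4.4 / 7)

    def test_summary_bundle(self, hex_net):
        s = summarize(hex_net)
        assert (s.n_nodes, s.n_links, s.n_components, s.largest_component) == (7, 12, 1, 7)
        assert s.components_per_node == pytest.approx(1 / 7)


class TestSimpleGraphs:
    def test_triangle_summary(self, triangle):
        s = summarize(build_contact_network(triangle))
        assert s.mean_degree == pytest.approx(2.0)
        assert s.transitivity == pytest.approx(1.0)
        assert s.mean_clustering == pytest.approx(1.0)
        assert s.knn == pytest.approx(2.0)  # regular graph: K_nn = degree

    def test_path_has_no_triangles(self):
        pos = np.array([[0.0, 0.0], [0.9, 0.0], [1.8, 0.0]])
        net = build_contact_network(pos)
        assert transitivity(net) == 0.0

    def test_star_clustering_zero(self):
        # hub with 4 leaves at distance 1, leaves mutually > 1 apart
        angles = np.linspace(0, 2 * np.pi, 4, endpoint=False)
        pos = np.vstack([[0.0, 0.0], np.column_stack([np.cos(angles), np.sin(angles)])])
        net = build_contact_network(pos)
        ci, mean_c = clustering(net)
        assert all(v == 0.0 for v in ci.values())
        assert mean_c == 0.0

    def test_disjoint_triangles_fully_clustered(self, triangle):
        pos = np.vstack([triangle.positions, triangle.positions + [100.0, 0.0]])
        net = build_contact_network(pos)
        assert transitivity(net) == pytest.approx(1.0)
        assert clustering(net)[1] == pytest.approx(1.0)
        _, sizes = connected_components(net)
        assert sorted(sizes) == [3, 3]

    def test_triangle_plus_pair_components(self, triangle):
        pos = np.vstack([triangle.positions, [[30.0, 0.0], [30.9, 0.0]]])
        s = summarize(build_contact_network(pos))
        assert s.n_components == 2
        assert s.component_sizes == [3, 2]
        assert s.largest_component == 3

    def test_empty_network_measures_raise(self):
        net = build_contact_network(np.array([[0.0, 0.0], [10.0, 0.0]]))
        for fn in (degree_distribution, average_degree, nearest_neighbor_degree,
                   transitivity, summarize):
            with pytest.raises(EmptyNetworkError):
                fn(net)


def _random_geometric(rng, n, box=None):
    if box is None:
        box = np.sqrt(n) * 1.1
    return rng.random((n, 2)) * box


class TestOracleEquivalence:
    def test_measures_match_brute_force_on_random_graphs(self, rng):
        import networkx as nx

        for _ in range(30):
            n = int(rng.integers(5, 51))
            pos = _random_geometric(rng, n)
            net = build_contact_network(pos)
            adj = brute_adjacency(pos)
            if net.n_nodes == 0:
                assert all(not s for s in adj.values())
                continue
            # edge sets agree
            edges = {(i, j) for i in adj for j in adj[i] if i < j}
            assert set(net.edges()) == edges
            # measures agree with independent oracles
            assert transitivity(net) == pytest.approx(brute_transitivity(adj), abs=1e-12)
            ci, mean_c = clustering(net)
            bci = brute_clustering(adj)
            assert ci == pytest.approx(bci, abs=1e-12)
            assert nearest_neighbor_degree(net) == pytest.approx(brute_knn(adj), abs=1e-12)
            # components: BFS vs union-find, and vs networkx
            labels, sizes = connected_components(net)
            uf = unionfind_components(adj)
            bfs_groups = {}
            for node, lab in labels.items():
                bfs_groups.setdefault(lab, set()).add(node)
            assert sorted((frozenset(g) for g in bfs_groups.values()),
                          key=lambda g: (-len(g), min(g))) == uf
            g = nx.Graph(edges)
            assert transitivity(net) == pytest.approx(nx.transitivity(g), abs=1e-12)
            assert mean_c == pytest.approx(nx.average_clustering(g), abs=1e-12)
            # handshake and normalization invariants
            assert average_degree(net) == pytest.approx(2 * net.n_links / net.n_nodes)
            assert sum(degree_distribution(net).values()) == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        pos = _random_geometric(rng, 40)
        perm = rng.permutation(40)
        a = summarize(build_contact_network(pos))
        b = summarize(build_contact_network(
            CellConfiguration(0.0, pos[perm], np.arange(40))))
        for attr in ("n_nodes", "n_links", "mean_degree", "knn", "transitivity",
                     "mean_clustering", "n_components", "largest_component"):
            assert getattr(a, attr) == pytest.approx(getattr(b, attr))
        assert a.component_sizes == b.component_sizes


class TestKissingBound:
    def test_hardcore_configurations_respect_max_degree_six(self, rng):
        for seed in range(5):
            config = fixture_hardcore_gas(60, box_side=10.0, min_dist=1.0, seed=seed)
            net = build_contact_network(config)
            if net.n_nodes:
                assert net.degrees.max() <= 6

    def test_hexagonal_packing_attains_six(self):
        net = build_contact_network(fixture_hexagonal(2))
        assert net.degrees.max() == 6
        # every cell with a complete shell has exactly six contacts
        assert int((net.degrees == 6).sum()) == 7
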