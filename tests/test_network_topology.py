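from itertools import combinations

import numpy as np
import pytest

from rmtnet import (
    SimilarityMatrix,
    clustering_coefficient,
    extract_network,
    fit_powerlaw_gamma,
    shared_edges,
    shared_nodes,
    topology_summary,
)
from rmtnet.network_topology import read_edge_list, write_edge_list
from rmtnet.rmt_threshold import prune_at_threshold
from rmtnet.errors import DegenerateDegrees, EmptyNetwork, InvalidParameter

from conftest import make_network


def random_sm(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1, 1, size=(n, n))
    corr = np.clip((a + a.T) / 2, -1, 1)
    np.fill_diagonal(corr, 1.0)
    return SimilarityMatrix([f"g{i}" for i in range(n)], corr, min_obs=1)


class TestExtract:
    def test_no_perfect_pairs_gives_empty_network(self):
        net = extract_network(random_sm(6, 0), 1.0)
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_four_gene_example(self):
        corr = np.eye(4)
        corr[0, 1] = corr[1, 0] = 0.95
        corr[2, 3] = corr[3, 2] = 0.97
        sm = SimilarityMatrix(["g1", "g2", "g3", "g4"], corr, min_obs=1)
        net = extract_network(sm, 0.9)
        assert net.edges == {("g1", "g2"): 0.95, ("g3", "g4"): 0.97}

    def test_negative_correlations_form_edges_with_signed_weight(self):
        corr = np.eye(2)
        corr[0, 1] = corr[1, 0] = -0.95
        net = extract_network(SimilarityMatrix(["a", "b"], corr, min_obs=1), 0.9)
        assert net.edges == {("a", "b"): -0.95}

    @pytest.mark.parametrize("t", [0.3, 0.5, 0.8])
    def test_node_set_matches_prune(self, t):
        sm = random_sm(15, 4)
        _, kept = prune_at_threshold(sm, t)
        assert extract_network(sm, t).nodes == set(kept)

    def test_edge_monotonicity_in_threshold(self):
        sm = random_sm(15, 5)
        assert extract_network(sm, 0.7).edge_set() <= extract_network(sm, 0.4).edge_set()


class TestSharedCounts:
    def test_identity(self, triangle):
        assert shared_nodes(triangle, triangle) == 3
        assert shared_edges(triangle, triangle) == 3

    def test_disjoint(self, triangle):
        other = make_network([("x", "y"), ("y", "z"), ("x", "z")])
        assert shared_nodes(triangle, other) == 0
        assert shared_edges(triangle, other) == 0

    def test_subset_and_symmetry(self, two_triangles, triangle):
        assert shared_nodes(triangle, two_triangles) == triangle.n_nodes
        assert shared_edges(triangle, two_triangles) == triangle.n_edges
        assert shared_edges(two_triangles, triangle) == shared_edges(triangle, two_triangles)
        assert shared_edges(triangle, two_triangles) <= min(
            triangle.n_edges, two_triangles.n_edges
        )


def brute_force_clustering(net):
    """Mean over nodes of 2T(v)/(k(k-1)) by exhaustive triangle counting."""
    adj = {v: set() for v in net.nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    total = 0.0
    for v, nb in adj.items():
        k = len(nb)
        if k < 2:
            continue
        t = sum(1 for x, y in combinations(sorted(nb), 2) if y in adj[x])
        total += 2 * t / (k * (k - 1))
    return total / len(adj)


class TestClustering:
    def test_triangle(self, triangle):
        assert clustering_coefficient(triangle) == 1.0

    def test_path_has_no_triangles(self):
        assert clustering_coefficient(make_network([("a", "b"), ("b", "c")])) == 0.0

    def test_clique_with_pendant(self, clique4_pendant):
        # a, b, c close all their triangles (1 each); the attachment node d
        # has degree 4 with 3 triangles (0.5); the pendant e contributes 0
        got = clustering_coefficient(clique4_pendant)
        assert got == pytest.approx(brute_force_clustering(clique4_pendant))
        assert got == pytest.approx((3 * 1.0 + 0.5 + 0.0) / 5)

    def test_matches_brute_force_on_random_graph(self, rng):
        pairs = {tuple(sorted(rng.choice(12, 2, replace=False))) for _ in range(30)}
        net = make_network([(f"n{a}", f"n{b}") for a, b in pairs])
        assert clustering_coefficient(net) == pytest.approx(brute_force_clustering(net))

    def test_empty(self):
        with pytest.raises(EmptyNetwork):
            clustering_coefficient(make_network([]))


class TestPowerlawGamma:
    def test_recovers_generating_exponent(self):
        rng = np.random.default_rng(0)
        ks = np.arange(1, 10**6 + 1)
        p = ks**-1.5
        degrees = rng.choice(ks, size=10_000, p=p / p.sum())
        assert fit_powerlaw_gamma(degrees, k_min=1) == pytest.approx(1.5, abs=0.1)

    def test_closed_form_on_small_multiset(self):
        degrees = [1, 1, 1, 1, 1, 2, 2, 2, 3, 4, 4, 8]
        expected = 1 + len(degrees) / sum(np.log(k / 0.5) for k in degrees)
        assert fit_powerlaw_gamma(degrees, k_min=1) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_degrees(self):
        with pytest.raises(DegenerateDegrees):
            fit_powerlaw_gamma([1] * 20, k_min=1)

    def test_too_few(self):
        with pytest.raises(InvalidParameter):
            fit_powerlaw_gamma([1, 2, 3], k_min=1)


class TestTopologySummary:
    def test_triangle(self, triangle):
        s = topology_summary(triangle)
        assert (s.n_nodes, s.n_edges) == (3, 3)
        assert s.avg_degree == pytest.approx(2.0)
        assert s.clustering_coefficient == 1.0
        assert s.gamma is None  # too few degrees for the MLE

    def test_avg_degree_identity(self, two_triangles):
        s = topology_summary(two_triangles)
        assert s.avg_degree == pytest.approx(2 * s.n_edges / s.n_nodes)

    def test_planted_network_is_clustered(self, planted_pipeline):
        *_, net = planted_pipeline
        s = topology_summary(net)
        assert 0.3 <= s.clustering_coefficient <= 1.0

    def test_empty(self):
        with pytest.raises(EmptyNetwork):
            topology_summary(make_network([]))


def test_edge_list_round_trip(tmp_path, two_triangles):
    path = tmp_path / "edges.tsv"
    write_edge_list(two_triangles, path)
    back = read_edge_list(path)
    assert back.edge_set() == two_triangles.edge_set()
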