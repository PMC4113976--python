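"""Binary-network metrics against brute-force and networkx oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import floyd_warshall_distances
from swmnet.shrinkage import PartialCorrNetwork, partial_correlations, shrink_covariance
from swmnet.synthetic import build_precision, simulate_cohort
from swmnet.topology import (
    best_partition,
    binarize,
    compare_density_matched,
    degrees,
    global_efficiency,
    hubs,
    integrate_over_densities,
    integrated_degrees,
    local_efficiency,
    modularity,
    permutation_metric_test,
)


def _efficiency_oracle(adj):
    """Direct inverse-harmonic-mean over Floyd–Warshall distances."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum() / (n * (n - 1))


def _local_efficiency_oracle(adj):
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size >= 2:
            total += _efficiency_oracle(adj[np.ix_(nbrs, nbrs)])
    return total / n


def _modularity_oracle(adj, labels):
    """Direct evaluation: Q = sum_c [e_cc - (sum_j e_cj)^2] with e the
    fraction-of-edge-ends matrix."""
    m = adj.sum() / 2.0
    if m == 0:
        return 0.0
    labels = np.asarray(labels)
    mods = np.unique(labels)
    e = np.zeros((len(mods), len(mods)))
    idx = {c: t for t, c in enumerate(mods)}
    n = adj.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                a, b = idx[labels[i]], idx[labels[j]]
                if a == b:
                    e[a, a] += 1.0 / m
                else:
                    e[a, b] += 0.5 / m
                    e[b, a] += 0.5 / m
    return float(np.trace(e) - (e.sum(axis=1) ** 2).sum())


def _all_set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _all_set_partitions(rest):
        for t in range(len(part)):
            yield part[:t] + [[first] + part[t]] + part[t + 1:]
        yield [[first]] + part


class TestMetricExamples:
    def test_complete_graph_efficiencies(self):
        adj = np.ones((6, 6), int) - np.eye(6, dtype=int)
        assert global_efficiency(adj) == 1.0
        assert local_efficiency(adj) == 1.0

    def test_path_graph_global_efficiency(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert global_efficiency(adj) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_star_graph(self):
        adj = np.zeros((6, 6), int)
        adj[0, 1:] = adj[1:, 0] = 1
        k = degrees(adj)
        assert k[0] == 5 and np.all(k[1:] == 1)
        assert local_efficiency(adj) == 0.0

    def test_single_module_q_zero(self):
        adj = np.ones((5, 5), int) - np.eye(5, dtype=int)
        assert modularity(adj, np.zeros(5, int)) == pytest.approx(0.0)

    def test_two_triangles_q_half(self):
        adj = np.zeros((6, 6), int)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 1
        q = modularity(adj, np.array([0, 0, 0, 1, 1, 1]))
        assert q == pytest.approx(0.5)


class TestOracleEquivalence:
    @pytest.fixture(scope="class")
    def graph_atlas(self):
        """All non-isomorphic graphs on up to 7 nodes."""
        return [g for g in nx.graph_atlas_g() if g.number_of_nodes() > 0]

    def test_efficiencies_match_brute_force_on_all_small_graphs(self, graph_atlas):
        for g in graph_atlas:
            adj = nx.to_numpy_array(g).astype(int)
            assert global_efficiency(adj) == pytest.approx(
                _efficiency_oracle(adj), abs=1e-8
            )
            assert local_efficiency(adj) == pytest.approx(
                _local_efficiency_oracle(adj), abs=1e-8
            )
            assert np.array_equal(degrees(adj), adj.sum(axis=1))

    def test_efficiency_matches_networkx_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = nx.gnp_random_graph(12, rng.uniform(0.1, 0.7), seed=int(rng.integers(1e6)))
            adj = nx.to_numpy_array(g).astype(int)
            assert global_efficiency(adj) == pytest.approx(
                nx.global_efficiency(g), abs=1e-10
            )

    def test_modularity_matches_direct_evaluation_all_partitions(self):
        """Q agrees with the direct fraction-matrix formula over every
        partition of every graph on up to 5 nodes."""
        rng = np.random.default_rng(1)
        graphs = [g for g in nx.graph_atlas_g()
                  if 1 <= g.number_of_nodes() <= 5]
        sampled = [graphs[i] for i in rng.choice(len(graphs), 25, replace=False)]
        for g in sampled:
            adj = nx.to_numpy_array(g).astype(int)
            n = adj.shape[0]
            for part in _all_set_partitions(list(range(n))):
                labels = np.empty(n, int)
                for t, block in enumerate(part):
                    labels[block] = t
                assert modularity(adj, labels) == pytest.approx(
                    _modularity_oracle(adj, labels), abs=1e-10
                )

    def test_modularity_matches_networkx(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            g = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            adj = nx.to_numpy_array(g).astype(int)
            labels = rng.integers(0, 3, 15)
            comms = [set(np.flatnonzero(labels == c)) for c in range(3)]
            comms = [c for c in comms if c]
            assert modularity(adj, labels) == pytest.approx(
                nx.community.modularity(g, comms), abs=1e-10
            )

    def test_best_partition_reaches_known_optimum(self):
        adj = np.zeros((6, 6), int)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 1
        labels, q = best_partition(adj, seed=0)
        assert q == pytest.approx(0.5)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]

    def test_best_partition_not_worse_than_networkx_greedy(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            g = nx.planted_partition_graph(3, 6, 0.8, 0.05,
                                           seed=int(rng.integers(1e6)))
            adj = nx.to_numpy_array(g).astype(int)
            _, q = best_partition(adj, seed=0)
            nx_comms = nx.community.greedy_modularity_communities(g)
            nx_q = nx.community.modularity(g, nx_comms)
            assert q >= nx_q - 0.05


class TestHubs:
    def test_distinct_degrees_give_upper_quartile_count(self):
        assert len(hubs(np.arange(78))) == 20

    def test_regular_graph_all_hubs(self):
        assert len(hubs(np.full(78, 5.0))) == 78


class TestBinarize:
    @pytest.fixture(scope="class")
    def net(self, atlas):
        model = build_precision(atlas, n_edges=100, seed=0)
        data = simulate_cohort(model, 60, seed=1)
        return partial_correlations(shrink_covariance(data.values), atlas=atlas)

    def test_density_extremes(self, net):
        assert binarize(net, density=1.0).n_edges == 3003
        assert binarize(net, density=0.0).n_edges == 0

    def test_density_mode_edge_count(self, net):
        b = binarize(net, density=0.05)
        assert b.n_edges == round(0.05 * 3003)

    def test_lfdr_mode_nestedness(self, net):
        loose = binarize(net, lfdr_threshold=0.5)
        strict = binarize(net, lfdr_threshold=0.2)
        assert loose.n_edges >= strict.n_edges
        assert np.all(loose.adjacency >= strict.adjacency)

    def test_density_nestedness_makes_ge_monotone(self, net):
        ge = [
            global_efficiency(binarize(net, density=d).adjacency)
            for d in (0.02, 0.05, 0.1, 0.2)
        ]
        assert np.all(np.diff(ge) >= 0)

    def test_argument_validation(self, net):
        with pytest.raises(ValueError):
            binarize(net)
        with pytest.raises(ValueError):
            binarize(net, density=1.5)


class TestDensityIntegration:
    @pytest.fixture(scope="class")
    def net(self, atlas):
        model = build_precision(atlas, n_edges=100, seed=4)
        data = simulate_cohort(model, 60, seed=5)
        return partial_correlations(shrink_covariance(data.values), atlas=atlas)

    def test_integrated_value_between_min_and_max(self, net):
        densities = np.linspace(0.02, 0.1, 5)
        vals = [
            global_efficiency(binarize(net, density=d).adjacency) for d in densities
        ]
        integrated = integrate_over_densities(net, "GE", densities=densities)
        assert min(vals) <= integrated <= max(vals)
        assert integrated == pytest.approx(np.mean(vals))

    def test_integrated_degree_shape(self, net):
        deg = integrated_degrees(net, densities=np.array([0.02, 0.05]))
        assert deg.shape == (78,)
        assert deg.max() > 0

    def test_constant_metric_integrates_to_itself(self, net):
        val = integrate_over_densities(net, "GE", densities=np.array([0.05, 0.05]))
        one = global_efficiency(binarize(net, density=0.05).adjacency)
        assert val == pytest.approx(one)


class TestGroupComparisons:
    def test_density_matched_identity(self, atlas):
        model = build_precision(atlas, n_edges=50, seed=6)
        data = simulate_cohort(model, 30, seed=7)
        net = partial_correlations(shrink_covariance(data.values), atlas=atlas)
        grid = np.array([0.02, 0.05, 0.1])
        out = compare_density_matched(net, net, grid, "GE")
        assert len(out) == 3
        assert np.allclose(out.value_a, out.value_b)

    def test_permutation_p_floor_and_null(self, atlas):
        """Identical populations: permutation p stays above the floor and
        is not significant."""
        model = build_precision(atlas, n_edges=100, seed=8)
        ds_a = simulate_cohort(model, 12, seed=9)
        ds_b = simulate_cohort(model, 12, seed=10)
        p = permutation_metric_test(
            ds_a, ds_b, metrics=("GE",), n_perm=100, seed=0, n_points=3,
            adjust=False,
        )
        assert p["GE"] >= 1.0 / 101.0
        assert p["GE"] > 0.05

    def test_permutation_detects_structure_difference(self, atlas):
        """A structured vs edgeless population at n=60/group: the integrated
        global efficiency differs and the label-permutation test notices.
        (At the n=15 study scale both groups yield empty networks and the
        test is vacuous, so the check runs in the powered regime.)"""
        model = build_precision(atlas, n_edges=100, seed=11)
        null_model = build_precision(atlas, n_edges=0, seed=12)
        ds_a = simulate_cohort(model, 60, seed=13)
        ds_b = simulate_cohort(null_model, 60, seed=14)
        p = permutation_metric_test(
            ds_a, ds_b, metrics=("GE",), n_perm=100, seed=1, n_points=3,
            adjust=False,
        )
        assert p["GE"] < 0.05
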