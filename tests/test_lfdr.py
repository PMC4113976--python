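"""Mixture fitting, lfdr computation, edge calling and the Fisher-z contrasts."""

import numpy as np
import pytest

from swmnet.lfdr import (
    DegenerateDistributionError,
    MixtureFit,
    call_edges,
    compare_groups,
    compare_hemispheres,
    edge_lfdr,
    fit_mixture,
)
from swmnet.shrinkage import partial_correlations, shrink_covariance
from swmnet.synthetic import build_precision, simulate_cohort, two_group_scenario


def _network(n_edges, n_subjects, seed, atlas):
    model = build_precision(atlas, n_edges=n_edges, seed=seed)
    data = simulate_cohort(model, n_subjects, seed=seed + 1000)
    net = partial_correlations(shrink_covariance(data.values), atlas=atlas)
    return model, net


class TestFitMixture:
    def test_requires_enough_values(self):
        with pytest.raises(ValueError):
            fit_mixture(np.linspace(-0.5, 0.5, 50))

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateDistributionError):
            fit_mixture(np.full(200, 0.1))

    def test_null_networks_give_high_eta0(self, atlas):
        """On fully null models the estimated null proportion is >= 0.95."""
        for seed in range(3):
            _, net = _network(0, 15, seed * 10, atlas)
            fit = fit_mixture(net.offdiag_values())
            assert 0.95 <= fit.eta0 <= 1.0

    def test_eta0_tracks_planted_proportion_when_detectable(self, atlas):
        """With ~3% planted edges and enough subjects, eta0 drops below 1 to
        the vicinity of the true null proportion (estimation leakage onto
        indirect within-component pairs biases it slightly low)."""
        _, net = _network(100, 100, 7, atlas)
        fit = fit_mixture(net.offdiag_values())
        assert 0.85 <= fit.eta0 <= 0.99

    def test_gaussian_family_scale_recovery(self):
        rng = np.random.default_rng(0)
        z = rng.normal(0, 2.0, 5000)
        fit = fit_mixture(z, null_family="gaussian")
        assert fit.null_param == pytest.approx(2.0, rel=0.1)
        with pytest.raises(AttributeError):
            fit.kappa


class TestEdgeLfdr:
    @pytest.fixture(scope="class")
    def fitted(self, atlas):
        _, net = _network(100, 60, 3, atlas)
        vals = net.offdiag_values()
        return fit_mixture(vals), vals

    def test_values_within_unit_interval(self, fitted):
        fit, vals = fitted
        lf = edge_lfdr(fit, vals)
        assert lf.min() >= 0.0 and lf.max() <= 1.0

    def test_monotone_non_increasing_in_magnitude(self, fitted):
        fit, vals = fitted
        lf = edge_lfdr(fit, vals)
        order = np.argsort(np.abs(vals))
        assert np.all(np.diff(lf[order]) <= 1e-12)

    def test_null_center_capped_at_one(self, fitted):
        fit, _ = fitted
        assert edge_lfdr(fit, np.array([0.0]))[0] == 1.0

    def test_matrix_output_symmetric_unit_diagonal(self, fitted):
        fit, _ = fitted
        rng = np.random.default_rng(1)
        mat = rng.uniform(-0.2, 0.2, (10, 10))
        mat = 0.5 * (mat + mat.T)
        np.fill_diagonal(mat, 1.0)
        lf = edge_lfdr(fit, mat)
        assert np.array_equal(lf, lf.T)
        assert np.all(np.diag(lf) == 1.0)


class TestCallEdges:
    def test_empty_network_all_disconnected(self, atlas):
        _, net = _network(0, 15, 21, atlas)
        es = call_edges(net, threshold=0.2)
        if len(es) == 0:
            assert es.disconnected == {"L": 39, "R": 39}
        assert sum(es.disconnected.values()) + len(
            set(es.edges.node_i) | set(es.edges.node_j)
        ) == 78

    def test_threshold_nestedness(self, atlas):
        _, net = _network(100, 60, 4, atlas)
        loose = call_edges(net, threshold=0.5)
        strict = call_edges(net, threshold=0.2)
        strict_set = set(map(tuple, strict.edges[["node_i", "node_j"]].values))
        loose_set = set(map(tuple, loose.edges[["node_i", "node_j"]].values))
        assert strict_set <= loose_set

    def test_called_edges_are_mostly_true_when_detectable(self, atlas):
        """The high-positive-predictive-value property of the lfdr<0.2 call,
        in the regime where the estimator has power (n=60)."""
        ppvs = []
        for seed in range(3):
            model, net = _network(100, 60, 30 + seed, atlas)
            es = call_edges(net, threshold=0.2)
            assert len(es) > 20
            called = {
                (min(i, j), max(i, j))
                for i, j in es.edges[["node_i", "node_j"]].values
            }
            ppvs.append(len(called & set(model.true_edges)) / len(called))
        assert np.mean(ppvs) > 0.8

    def test_sign_flip_invariance(self, atlas):
        """Edge calls are unchanged under a global sign flip of the data."""
        model = build_precision(atlas, n_edges=100, seed=5)
        data = simulate_cohort(model, 60, seed=6)
        net_pos = partial_correlations(shrink_covariance(data.values), atlas=atlas)
        net_neg = partial_correlations(shrink_covariance(-data.values), atlas=atlas)
        es_pos = call_edges(net_pos)
        es_neg = call_edges(net_neg)
        assert es_pos.edges[["node_i", "node_j"]].values.tolist() == \
            es_neg.edges[["node_i", "node_j"]].values.tolist()

    def test_tally_marginals(self, atlas):
        _, net = _network(100, 60, 8, atlas)
        es = call_edges(net)
        by_class = es.counts_by_class()
        assert sum(by_class.values()) == len(es)
        by_sign = es.counts_by_sign()
        assert sum(v for d in by_sign.values() for v in d.values()) == len(es)


class TestCompareGroups:
    def test_identical_networks_no_differences(self, atlas):
        _, net = _network(50, 30, 9, atlas)
        es = compare_groups(net, net, 30, 30)
        assert len(es) == 0

    def test_fisher_z_closed_form(self, atlas):
        """p_a = 0.5, p_b = 0, n = 15 each: z = atanh(0.5)/sqrt(2/12) ~ 1.3457."""
        rng = np.random.default_rng(10)
        pa = rng.uniform(-0.05, 0.05, (78, 78))
        pb = rng.uniform(-0.05, 0.05, (78, 78))
        pa = 0.5 * (pa + pa.T)
        pb = 0.5 * (pb + pb.T)
        np.fill_diagonal(pa, 1.0)
        np.fill_diagonal(pb, 1.0)
        pa[2, 5] = pa[5, 2] = 0.5
        pb[2, 5] = pb[5, 2] = 0.0
        from swmnet.shrinkage import PartialCorrNetwork

        net_a = PartialCorrNetwork(pmat=pa, atlas=atlas)
        net_b = PartialCorrNetwork(pmat=pb, atlas=atlas)
        es = compare_groups(net_a, net_b, 15, 15, threshold=1.1)
        row = es.edges[(es.edges.node_i == 2) & (es.edges.node_j == 5)]
        assert row.iloc[0].statistic == pytest.approx(
            np.arctanh(0.5) / np.sqrt(2.0 / 12.0), abs=1e-4
        )
        assert es.jarque_bera_p is not None

    def test_lost_edge_recovered_at_large_n(self, atlas):
        hits = 0
        for seed in range(5):
            model = build_precision(atlas, n_edges=30, seed=40 + seed,
                                    partial_corr_range=(0.4, 0.5))
            lost = {sorted(model.true_edges)[0]}
            ds_a, ds_b = two_group_scenario(
                model, lost, None, n_per_group=500, seed=50 + seed
            )
            na = partial_correlations(shrink_covariance(ds_a.values), atlas=atlas)
            nb = partial_correlations(shrink_covariance(ds_b.values), atlas=atlas)
            es = compare_groups(na, nb, 500, 500, labels=("control", "AD"))
            found = {
                (min(i, j), max(i, j))
                for i, j in es.edges[["node_i", "node_j"]].values
            }
            directions = dict(
                zip(
                    [tuple(sorted(t)) for t in es.edges[["node_i", "node_j"]].values],
                    es.edges.direction,
                )
            )
            e = next(iter(lost))
            if e in found and directions[e] == "AD<control":
                hits += 1
        assert hits >= 4

    def test_mismatched_networks_rejected(self, atlas):
        from swmnet.shrinkage import PartialCorrNetwork

        a = PartialCorrNetwork(pmat=np.eye(10))
        b = PartialCorrNetwork(pmat=np.eye(12))
        with pytest.raises(ValueError):
            compare_groups(a, b, 15, 15)


class TestCompareHemispheres:
    def test_pair_count_contract(self, atlas):
        _, net = _network(50, 500, 60, atlas)
        es = compare_hemispheres(net, atlas, 500, threshold=1.1)
        assert len(es) == 741  # every LH pair maps onto one RH pair

    def test_symmetric_null_rarely_flags(self, atlas):
        """Mirror-symmetric population: asymmetric edges stay near the noise floor."""
        false_rates = []
        for seed in range(3):
            _, net = _network(0, 500, 70 + seed * 5, atlas)
            es = compare_hemispheres(net, atlas, 500)
            false_rates.append(len(es) / 741)
        assert np.mean(false_rates) < 0.05

    def test_planted_lh_edge_flagged(self, atlas):
        hits = 0
        for seed in range(5):
            model = build_precision(
                atlas, n_edges=1, edges=[(2, 7)], partial_corr_range=(0.5, 0.5),
                positive_fraction=1.0, seed=seed,
            )
            data = simulate_cohort(model, 500, seed=100 + seed)
            net = partial_correlations(shrink_covariance(data.values), atlas=atlas)
            es = compare_hemispheres(net, atlas, 500)
            sel = es.edges[(es.edges.node_i == 2) & (es.edges.node_j == 7)]
            if len(sel) and sel.iloc[0].direction == "LH>RH":
                hits += 1
        assert hits >= 4

    def test_atlas_required(self):
        from swmnet.shrinkage import PartialCorrNetwork

        with pytest.raises(ValueError):
            compare_hemispheres(PartialCorrNetwork(pmat=np.eye(78)), None, 15)
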