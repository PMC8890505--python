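"""Bootstrapped network construction: subsample enumeration, density
thresholding, aggregation, and the sign partition."""

import numpy as np
import pandas as pd
import pytest

from sdmnet import (
    ActivationModel,
    ConnectivityConfig,
    CorrelationBlock,
    NetworkInstance,
    aggregate,
    build_treatment_network,
    enumerate_subsamples,
    generate_activation,
    instance_network,
    robustness_rank_correlation,
    split_signed,
)
from sdmnet.catalog import REGIONS

from _oracles import threshold_edges_bruteforce


class TestEnumerateSubsamples:
    def test_nine_choose_seven(self):
        cfg = ConnectivityConfig(subsample_size=7)
        subsets = enumerate_subsamples([f"f{i}" for i in range(9)], cfg)
        assert len(subsets) == 36
        assert all(len(s) == 7 for s in subsets)
        assert subsets == sorted(subsets)  # lexicographic order

    def test_leave_one_out_fallback(self):
        cfg = ConnectivityConfig(subsample_size=7)
        subsets = enumerate_subsamples([f"f{i}" for i in range(7)], cfg)
        assert len(subsets) == 7
        assert all(len(s) == 6 for s in subsets)

    def test_strict_s_errors_instead(self):
        cfg = ConnectivityConfig(subsample_size=7, strict_s=True)
        with pytest.raises(ValueError, match="strict"):
            enumerate_subsamples(list(range(6)), cfg)

    def test_random_policy_deterministic_under_seed(self):
        cfg = ConnectivityConfig(
            subsample_size=4, policy="random_m", m=10, seed=123
        )
        ids = list(range(12))
        assert enumerate_subsamples(ids, cfg) == enumerate_subsamples(ids, cfg)
        assert len(set(enumerate_subsamples(ids, cfg))) == 10

    def test_tiny_stratum_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            enumerate_subsamples([1, 2], ConnectivityConfig())


class TestInstanceNetwork:
    def test_exact_retention_count(self, rng):
        counts = rng.poisson(30, size=(7, 19))
        inst = instance_network(counts, ConnectivityConfig())
        assert inst.n_retained == 39  # round(0.23 * 171)

    def test_retained_set_matches_bruteforce_sort(self, rng):
        regions = ("r1", "r2", "r3", "r4")
        counts = rng.normal(50, 10, size=(6, 4))
        cfg = ConnectivityConfig(density=0.5)
        inst = instance_network(counts, cfg, regions=regions)
        corr = np.corrcoef(counts, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        expected = threshold_edges_bruteforce(corr, cfg.n_retained(4))
        got = {
            (i, j)
            for i in range(4)
            for j in range(i + 1, 4)
            if inst.mask[i, j]
        }
        assert got == expected

    def test_collinear_pair_always_retained(self, rng):
        counts = rng.normal(0, 1, size=(8, 19))
        counts[:, 1] = 2.0 * counts[:, 0] + 5.0  # perfectly collinear
        inst = instance_network(counts, ConnectivityConfig())
        assert inst.mask[0, 1]
        assert inst.weights[0, 1] == pytest.approx(1.0)

    def test_zero_variance_region_gets_zero_correlations(self, rng):
        counts = rng.normal(0, 1, size=(8, 19))
        counts[:, 3] = 4.2
        inst = instance_network(counts, ConnectivityConfig())
        assert (inst.weights[3, :] == 0).all()

    def test_weights_symmetric_zero_diagonal(self, rng):
        inst = instance_network(rng.poisson(30, (7, 19)), ConnectivityConfig())
        np.testing.assert_allclose(inst.weights, inst.weights.T)
        assert (np.diag(inst.weights) == 0).all()
        assert (np.abs(inst.weights) <= 1).all()


class TestAggregate:
    def _instance(self, weights, regions):
        w = np.asarray(weights, dtype=float)
        return NetworkInstance(
            weights=w, mask=w != 0, regions=regions, subsample=()
        )

    def test_single_instance_identity(self, rng):
        inst = instance_network(rng.poisson(30, (7, 19)), ConnectivityConfig())
        net = aggregate([inst], sex="F", condition="winner")
        np.testing.assert_allclose(net.weights, inst.weights)

    def test_half_retention_mean_with_zeros(self):
        regions = ("a", "b")
        w = [[0.0, 0.8], [0.8, 0.0]]
        z = [[0.0, 0.0], [0.0, 0.0]]
        net = aggregate([self._instance(w, regions), self._instance(z, regions)])
        assert net.weights[0, 1] == pytest.approx(0.4)

    def test_mean_over_retaining_alternative(self):
        regions = ("a", "b")
        w = [[0.0, 0.8], [0.8, 0.0]]
        z = [[0.0, 0.0], [0.0, 0.0]]
        instances = [self._instance(w, regions), self._instance(z, regions)]
        net = aggregate(instances, rule="mean_over_retaining")
        assert net.weights[0, 1] == pytest.approx(0.8)

    def test_aggregate_bounded_by_max_instance_weight(self, rng):
        instances = [
            instance_network(rng.poisson(30, (7, 19)), ConnectivityConfig())
            for _ in range(5)
        ]
        net = aggregate(instances)
        max_abs = np.max(np.abs(np.stack([i.weights for i in instances])), axis=0)
        assert (np.abs(net.weights) <= max_abs + 1e-12).all()


class TestSplitSigned:
    def test_all_positive_network_has_empty_inhibition(self):
        model = ActivationModel(
            group_sizes={("F", "winner"): 8},
            blocks=[CorrelationBlock(tuple(REGIONS[:6]), 0.9)],
            seed=2,
        )
        table = generate_activation(model)
        net = build_treatment_network(table, "F", "winner")
        sub = split_signed(net)
        assert (sub.excitation["weight"] > 0).all()
        assert (sub.inhibition["weight"] < 0).all()

    def test_negation_swaps_subnetworks(self, blocked_activation):
        net = build_treatment_network(blocked_activation, "F", "winner")
        sub = split_signed(net)
        negated = type(net)(
            sex=net.sex,
            condition=net.condition,
            weights=-net.weights,
            regions=net.regions,
            n_instances=net.n_instances,
        )
        flipped = split_signed(negated)
        exc = sub.excitation.assign(weight=lambda d: -d["weight"])
        pd.testing.assert_frame_equal(
            flipped.inhibition.reset_index(drop=True), exc.reset_index(drop=True)
        )

    def test_sign_partition_covers_all_nonzero_edges(self, blocked_activation):
        net = build_treatment_network(blocked_activation, "M", "loser")
        sub = split_signed(net)
        assert len(sub.excitation) + len(sub.inhibition) == len(net.edge_list())


class TestPipelineProperties:
    def test_region_relabeling_equivariance(self, blocked_activation):
        """Permuting region columns permutes the network identically."""
        net = build_treatment_network(blocked_activation, "F", "control")
        perm = np.arange(len(REGIONS))[::-1]
        permuted_regions = tuple(np.array(REGIONS)[perm])
        permuted_table = blocked_activation[
            ["fish_id", "sex", "condition", *permuted_regions]
        ]
        net_p = build_treatment_network(
            permuted_table, "F", "control", regions=permuted_regions
        )
        np.testing.assert_allclose(
            net_p.weights, net.weights[np.ix_(perm, perm)], atol=1e-12
        )

    def test_planted_block_tops_excitation(self):
        """Edges of a strong positive block dominate the aggregated weights."""
        model = ActivationModel(
            group_sizes={("M", "winner"): 9},
            blocks=[CorrelationBlock(("Vs", "Hv", "TPp"), 0.9)],
            seed=31,
        )
        net = build_treatment_network(generate_activation(model), "M", "winner")
        edges = net.edge_list().sort_values("weight", ascending=False)
        top3 = {
            frozenset((r.region_i, r.region_j)) for r in edges.head(3).itertuples()
        }
        expected = {
            frozenset(p) for p in (("Vs", "Hv"), ("Vs", "TPp"), ("Hv", "TPp"))
        }
        assert top3 == expected

    def test_robustness_rank_correlation_bounded_and_high(self):
        model = ActivationModel(
            group_sizes={("F", "loser"): 9},
            blocks=[CorrelationBlock(("Vs", "Hv", "TPp"), 0.9)],
            seed=17,
        )
        table = generate_activation(model)
        rho = robustness_rank_correlation(table, "F", "loser")
        assert -1.0 <= rho <= 1.0
        assert rho > 0.5  # strong planted structure is stable in s


def test_density_rounding_rules():
    assert ConnectivityConfig().n_retained(19) == 39
    assert ConnectivityConfig(rounding="floor").n_retained(19) == 39
    assert ConnectivityConfig(rounding="ceil").n_retained(19) == 40
    assert ConnectivityConfig(density=1.0).n_retained(19) == 171
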