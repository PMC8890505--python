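"""Contest statistics: dyad summaries, the gated two-group test, PCA of
display totals, and the permutation MANOVA, each checked against
independent oracles where one exists."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmnet import (
    behavior_pca,
    gated_two_group_test,
    generate_dyads,
    permanova,
    sex_comparison_table,
    summarize_dyad,
    summarize_dyads,
)
from sdmnet.catalog import BEHAVIORS
from sdmnet.synthetic import BehaviorModel

from _oracles import mwu_exact_p, permanova_exhaustive_p, permanova_f_centroid


def _events(rows):
    return pd.DataFrame(rows, columns=["behavior", "t_seconds"])


class TestSummarize:
    def test_frequency_arithmetic(self):
        events = _events([("bite", 10.0 * i) for i in range(1, 11)])
        row = summarize_dyad(
            events, {"dyad_id": "d1", "sex": "F", "resolution_min": 5.0}
        )
        assert row["total_bite"] == 10
        assert row["freq_bite"] == pytest.approx(2.0)
        assert row["freq_aggressive"] == pytest.approx(2.0)
        assert row["freq_submissive"] == 0.0

    def test_latency_is_first_aggressive_act(self):
        events = _events([("flee", 30.0), ("bite", 90.0), ("strike", 120.0)])
        row = summarize_dyad(
            events, {"dyad_id": "d", "sex": "M", "resolution_min": 10.0}
        )
        assert row["latency_min"] == pytest.approx(1.5)

    def test_no_aggressive_events_latency_missing(self):
        events = _events([("flee", 10.0), ("freeze", 20.0)])
        row = summarize_dyad(
            events, {"dyad_id": "d", "sex": "M", "resolution_min": 2.0}
        )
        assert np.isnan(row["latency_min"])

    def test_unknown_behavior_rejected(self):
        events = _events([("yawning", 5.0)])
        with pytest.raises(ValueError, match="yawning"):
            summarize_dyad(events, {"dyad_id": "d", "sex": "F", "resolution_min": 1.0})

    def test_zero_resolution_rejected(self):
        with pytest.raises(ValueError, match="resolution"):
            summarize_dyad(
                _events([]), {"dyad_id": "d", "sex": "F", "resolution_min": 0.0}
            )

    def test_round_trip_against_generator(self, small_dyads):
        """Summaries recomputed from events match the generator's ledger."""
        events, gen_summaries = small_dyads
        meta = gen_summaries[["dyad_id", "sex", "resolution_min"]]
        recomputed = summarize_dyads(events, meta)
        for b in BEHAVIORS:
            np.testing.assert_array_equal(
                recomputed[f"total_{b}"].to_numpy(),
                gen_summaries[f"total_{b}"].to_numpy(),
            )
        np.testing.assert_allclose(
            recomputed["latency_min"], gen_summaries["latency_min"]
        )


class TestGatedTwoGroupTest:
    def test_identical_samples_no_difference(self):
        res = gated_two_group_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        if res.test == "t":
            assert res.statistic == pytest.approx(0.0)
        else:
            assert res.pvalue == pytest.approx(1.0)

    def test_separated_samples_exact_mwu(self):
        """x entirely below y: U = 0 and exact two-sided p = 2/C(10,5).

        An alpha gate of 1.0 makes the normality gate unpassable, forcing
        the Mann-Whitney branch.
        """
        x = [1.0, 1.5, 2.0, 2.2, 2.9]
        y = [10.0, 11.0, 12.0, 13.0, 14.0]
        u_oracle, p_oracle = mwu_exact_p(x, y)
        assert u_oracle == 0.0
        assert p_oracle == pytest.approx(2 / 252)
        res = gated_two_group_test(x, y, alpha_gate=1.0)
        assert res.test == "mann_whitney"
        # W (rank sum) = U + n1(n1+1)/2 = 0 + 15
        assert res.statistic == pytest.approx(15.0)
        assert res.pvalue == pytest.approx(p_oracle)

    def test_w_convention_is_rank_sum(self, rng):
        """Reported W equals the pooled rank sum of the first sample."""
        x = rng.exponential(size=12) ** 3  # heavy-tailed: fails the gate
        y = rng.exponential(size=15) ** 3
        res = gated_two_group_test(x, y)
        assert res.test == "mann_whitney"
        from scipy.stats import rankdata

        ranks = rankdata(np.concatenate([x, y]))
        assert res.statistic == pytest.approx(ranks[:12].sum())

    @pytest.mark.parametrize("n_pair", [(4, 5), (6, 6), (8, 7)])
    def test_mwu_branch_matches_enumeration_oracle(self, rng, n_pair):
        n1, n2 = n_pair
        x = rng.exponential(size=n1) ** 3
        y = rng.exponential(size=n2) ** 3
        res = gated_two_group_test(x, y)
        assert res.test == "mann_whitney"
        _, p_oracle = mwu_exact_p(x, y)
        assert res.pvalue == pytest.approx(p_oracle)

    def test_normal_samples_take_t_branch(self, rng):
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        res = gated_two_group_test(x, y)
        assert res.test == "t"
        assert res.normal_x and res.normal_y

    def test_constant_sample_routes_to_mann_whitney(self):
        res = gated_two_group_test([2.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.test == "mann_whitney"
        assert not res.normal_x

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            gated_two_group_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBehaviorPCA:
    def test_single_axis_of_variance(self):
        x = np.zeros((10, 3))
        x[:, 0] = np.arange(10.0)
        res = behavior_pca(x, sqrt_transform=False)
        assert res.proportion[0] == pytest.approx(1.0)
        assert res.proportion[1:] == pytest.approx(0.0)

    def test_loadings_orthonormal_and_proportions_sum_to_one(self, rng):
        x = rng.poisson(10.0, size=(30, 5)).astype(float)
        res = behavior_pca(x)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(5), atol=1e-10)
        assert res.proportion.sum() == pytest.approx(1.0)
        assert (np.diff(res.cumulative) >= -1e-12).all()

    def test_scores_covariance_diagonal(self, rng):
        x = rng.poisson(20.0, size=(100, 4)).astype(float)
        res = behavior_pca(x)
        cov = np.cov(res.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        np.testing.assert_allclose(off, 0.0, atol=1e-10)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), res.sdev, atol=1e-10)

    def test_isotropic_cloud_splits_variance(self, rng):
        x = rng.normal(100.0, 1.0, size=(2000, 2)) ** 2  # sqrt -> ~isotropic
        res = behavior_pca(x)
        assert res.proportion[0] == pytest.approx(0.5, abs=0.05)

    def test_matches_sklearn_oracle(self, rng):
        """Dual route: from-scratch eigendecomposition vs sklearn PCA."""
        from sklearn.decomposition import PCA

        x = rng.poisson(15.0, size=(40, 6)).astype(float)
        res = behavior_pca(x)
        ref = PCA().fit(np.sqrt(x))
        np.testing.assert_allclose(
            res.proportion, ref.explained_variance_ratio_, atol=1e-10
        )
        for j in range(6):
            ours = res.loadings.to_numpy()[:, j]
            theirs = ref.components_[j]
            assert min(
                np.abs(ours - theirs).max(), np.abs(ours + theirs).max()
            ) < 1e-8

    def test_negative_totals_rejected(self):
        with pytest.raises(ValueError):
            behavior_pca(np.array([[1.0, -1.0], [2.0, 3.0]]))


class TestPermanova:
    def test_f_matches_centroid_oracle(self, rng):
        x = rng.normal(size=(14, 3))
        labels = np.array(["a"] * 7 + ["b"] * 7)
        res = permanova(x, labels, n_permutations=99, seed=0)
        assert res.pseudo_f == pytest.approx(permanova_f_centroid(x, labels))
        assert res.ss_total == pytest.approx(res.ss_between + res.ss_within)

    def test_exhaustive_p_matches_enumeration_oracle(self, rng):
        """2 groups x 3 individuals: exact p over all 20 assignments."""
        x = rng.normal(size=(6, 2))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(x, labels, exhaustive=True)
        assert res.pvalue == pytest.approx(permanova_exhaustive_p(x, labels))
        assert res.n_permutations == 20

    def test_all_equal_observations_guarded(self):
        x = np.ones((8, 3))
        labels = ["a"] * 4 + ["b"] * 4
        res = permanova(x, labels, n_permutations=49, seed=1)
        assert res.pseudo_f == 0.0
        assert res.pvalue == 1.0

    def test_group_of_one_rejected(self, rng):
        with pytest.raises(ValueError, match="2 members"):
            permanova(rng.normal(size=(5, 2)), ["a", "b", "b", "b", "b"])

    def test_matches_skbio_oracle(self, rng):
        """Cross-check pseudo-F and the permutation scheme against scikit-bio."""
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        x = rng.normal(size=(16, 4))
        x[8:] += 0.8
        labels = ["a"] * 8 + ["b"] * 8
        from scipy.spatial.distance import pdist, squareform

        dm = DistanceMatrix(squareform(pdist(x)))
        ref = skbio_permanova(dm, grouping=labels, permutations=999)
        res = permanova(x, labels, n_permutations=999, seed=3)
        assert res.pseudo_f == pytest.approx(ref["test statistic"])
        assert res.pvalue == pytest.approx(ref["p-value"], abs=0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(shift=st.floats(-50, 50, allow_nan=False), seed=st.integers(0, 10**6))
    def test_invariant_to_constant_shift(self, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(10, 3))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        f1 = permanova(x, labels, n_permutations=9, seed=0).pseudo_f
        f2 = permanova(x + shift, labels, n_permutations=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2)

    def test_invariant_to_rotation(self, rng):
        x = rng.normal(size=(12, 3))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        f1 = permanova(x, labels, n_permutations=9, seed=0).pseudo_f
        f2 = permanova(x @ q, labels, n_permutations=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2)


def test_sex_comparison_table_covers_all_metrics():
    model = BehaviorModel(seed=21)
    _, summaries = generate_dyads(model, 10)
    table = sex_comparison_table(summaries)
    assert set(table["test"]) <= {"t", "mann_whitney"}
    assert len(table) == 2 + len(BEHAVIORS) + 2
    assert ((table["pvalue"] >= 0) & (table["pvalue"] <= 1)).all()
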