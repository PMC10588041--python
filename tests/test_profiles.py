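"""Profile contributions, balance statistics and differential shift ranking."""

import warnings

import numpy as np
import pandas as pd
import pytest

from fibrenmf.containers import SchemaError
from fibrenmf.profiles import (
    average_counts,
    average_weights,
    barycentric_w12,
    contribution,
    first_timepoint_mask,
    group_contribution_shift,
    ternary_coords,
    two_group_tests,
)


class TestAverages:
    def test_single_sample_is_itself(self):
        np.testing.assert_array_equal(average_weights([[1.0, 2.0]]), [1.0, 2.0])

    def test_mean_of_two(self):
        np.testing.assert_allclose(average_weights([[0, 1], [1, 0]]), [0.5, 0.5])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(size=(7, 3))
        perm = rng.permutation(7)
        np.testing.assert_allclose(average_weights(W), average_weights(W[perm]))
        np.testing.assert_allclose(average_counts(W), average_counts(W[perm]))


class TestContribution:
    def test_exact_mixture_sums_to_one(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(0.1, 1, size=(10, 3))
        H = rng.uniform(0.1, 1, size=(3, 5))
        X = W @ H
        rep = contribution(average_weights(W), H, average_counts(X))
        np.testing.assert_allclose(rep.contribution.sum(axis=0), 1.0, atol=1e-10)
        np.testing.assert_allclose(rep.residual, 0.0, atol=1e-10)

    def test_half_contribution_hand_case(self):
        rep = contribution(np.array([2.0]), np.array([[0.5]]), np.array([2.0]))
        assert rep.contribution[0, 0] == pytest.approx(0.5)
        assert rep.residual[0] == pytest.approx(0.5)

    def test_zero_profile_column_gives_full_residual(self):
        rep = contribution(np.array([1.0]), np.array([[0.0]]), np.array([2.0]))
        assert rep.contribution[0, 0] == 0.0
        assert rep.residual[0] == pytest.approx(1.0)

    def test_zero_mean_feature_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero-mean"):
            rep = contribution(np.array([1.0]), np.array([[1.0, 1.0]]),
                               np.array([2.0, 0.0]), feature_ids=["a", "b"])
        assert rep.excluded == ["b"]
        assert np.isnan(rep.contribution[0, 1])


class TestBalance:
    def test_four_to_one_ratio_gives_point_two(self):
        assert barycentric_w12(np.array([[4.0, 1.0]]))[0] == pytest.approx(0.2)

    def test_equal_weights_give_half(self):
        assert barycentric_w12(np.array([[0.7, 0.7, 1.0]]))[0] == pytest.approx(0.5)

    def test_zero_pair_is_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = barycentric_w12(np.array([[0.0, 0.0, 1.0]]))
        assert np.isnan(out[0])

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        W = rng.uniform(0.1, 1, size=(6, 3))
        scale = rng.uniform(0.5, 5, size=(6, 1))
        np.testing.assert_allclose(barycentric_w12(W), barycentric_w12(W * scale))
        np.testing.assert_allclose(ternary_coords(W), ternary_coords(W * scale))


class TestTernary:
    def test_uniform_triple(self):
        np.testing.assert_allclose(ternary_coords(np.array([[1.0, 1.0, 1.0]]))[0],
                                   [1 / 3, 1 / 3, 1 / 3])

    def test_single_corner(self):
        np.testing.assert_allclose(ternary_coords(np.array([[2.0, 0.0, 0.0]]))[0],
                                   [1, 0, 0])

    def test_four_one_zero(self):
        np.testing.assert_allclose(ternary_coords(np.array([[4.0, 1.0, 0.0]]))[0],
                                   [0.8, 0.2, 0.0])

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        W = rng.uniform(0.1, 1, size=(8, 4))
        out = ternary_coords(W, profile_triple=(0, 1, 3))
        np.testing.assert_allclose(out.sum(axis=1), 1.0)


class TestDeduplication:
    def test_first_timepoint_kept_per_individual(self):
        md = pd.DataFrame(
            {
                "Patient_ID": ["p1", "p1", "p2", "p3", "p3"],
                "Timepoint": [4, 0, 0, 8, 2],
            },
            index=[f"s{i}" for i in range(5)],
        )
        mask = first_timepoint_mask(md)
        np.testing.assert_array_equal(mask, [False, True, True, False, True])


class TestContributionShift:
    def _planted(self, shifted: bool, seed=0, n_per=40):
        """Two groups over 12 features; group 2 optionally has profile 3 elevated."""
        rng = np.random.default_rng(seed)
        k, p = 3, 12
        H = rng.uniform(0.1, 1.0, size=(k, p)) * (rng.uniform(size=(k, p)) < 0.7)
        H[2, :] = 0.0
        H[2, 8:] = 1.0  # profile 3 exclusively drives features 8..11
        W1 = np.column_stack([
            rng.gamma(20.0, 0.05, n_per), rng.gamma(20.0, 0.0125, n_per),
            rng.gamma(20.0, 0.0025, n_per),
        ])
        W2 = W1.copy()
        if shifted:
            W2[:, 2] = rng.gamma(20.0, 0.025, n_per)  # 10x profile-3 weight
        W = np.vstack([W1, W2])
        X = (W @ H) * rng.lognormal(-0.005, 0.1, size=(2 * n_per, p))
        groups = ["g1"] * n_per + ["g2"] * n_per
        return X, W, H, np.array(groups)

    def test_identical_groups_yield_empty_table(self):
        X, W, H, groups = self._planted(shifted=False, seed=1)
        out = group_contribution_shift(X, W, H, groups)
        assert out.empty

    def test_planted_profile3_shift_tops_the_ranking(self):
        X, W, H, groups = self._planted(shifted=True, seed=2)
        out = group_contribution_shift(X, W, H, groups, n_top=20)
        assert not out.empty
        top = set(out.head(4).feature_id)
        assert top <= {"f8", "f9", "f10", "f11"}
        # the shifted features' dominant contribution change is in profile 3
        lead = out.iloc[0]
        assert abs(lead.g1_profile_3 - lead.g2_profile_3) > abs(
            lead.g1_profile_1 - lead.g2_profile_1
        )

    def test_truncation_to_one(self):
        X, W, H, groups = self._planted(shifted=True, seed=3)
        out = group_contribution_shift(X, W, H, groups, n_top=1)
        assert len(out) == 1

    def test_group_size_check(self):
        X, W, H, groups = self._planted(shifted=True, seed=4, n_per=2)
        with pytest.raises(SchemaError, match="at least 3"):
            group_contribution_shift(X, W, H, groups)

    def test_dedup_applied_through_metadata(self):
        X, W, H, groups = self._planted(shifted=True, seed=5, n_per=10)
        md = pd.DataFrame(
            {
                "Patient_ID": [f"p{i // 2}" for i in range(20)],  # pairs share individuals
                "Timepoint": [i % 2 for i in range(20)],
            },
            index=[f"s{i}" for i in range(20)],
        )
        out = group_contribution_shift(X, W, H, groups, metadata=md)
        assert isinstance(out, pd.DataFrame)  # runs on the deduplicated half


def test_two_group_tests_wrapper():
    rng = np.random.default_rng(6)
    res = two_group_tests(rng.normal(0, 1, 50), rng.normal(2, 1, 50))
    assert res["mannwhitney_p"] < 1e-6
    assert 0 <= res["levene_p"] <= 1
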