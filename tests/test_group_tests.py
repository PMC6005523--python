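"""ANOSIM, SIMPER and chi-square: oracles, enumeration and calibration."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietpulse.core_data import CountTable, ValidationError
from dietpulse.group_tests import (
    GroupLabels,
    anosim,
    chi_square_independence,
    simper,
)

from conftest import euclidean_dm
from test_dissimilarity import cm


def anosim_r_oracle(d, labels):
    """Independent R computation straight from the definition."""
    n = len(labels)
    ranks = stats.rankdata(d[np.triu_indices(n, k=1)])
    pairs = list(itertools.combinations(range(n), 2))
    within = np.array([labels[i] == labels[j] for i, j in pairs])
    return (ranks[~within].mean() - ranks[within].mean()) / (n * (n - 1) / 4)


class TestAnosim:
    def test_full_separation_gives_R_one(self):
        # two tight clusters far apart: every between distance beats every
        # within distance
        pts = [[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]]
        D = euclidean_dm(pts)
        res = anosim(D, GroupLabels(np.array(list("aaabbb"))), n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(0)
        D = euclidean_dm(rng.normal(size=(12, 3)))
        res = anosim(D, GroupLabels(np.array(["a", "b"] * 6)), n_perm=2000, seed=1)
        assert abs(res.null_R.mean()) < 3 * res.null_R.std() / np.sqrt(2000)

    def test_matches_independent_oracle_R(self):
        rng = np.random.default_rng(5)
        D = euclidean_dm(rng.normal(size=(8, 2)))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        res = anosim(D, GroupLabels(labels), n_perm=9, seed=0)
        assert res.R == pytest.approx(anosim_r_oracle(D.d, labels), abs=1e-12)

    def test_matches_reference_implementation(self):
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 2))
        D = euclidean_dm(pts)
        labels = ["a"] * 5 + ["b"] * 5
        ours = anosim(D, GroupLabels(np.array(labels)), n_perm=9, seed=0)
        ref = sk_anosim(SkDM(D.d), grouping=labels, permutations=9)
        assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_permutation_p_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for trial in range(3):
            pts = rng.normal(size=(7, 2))
            labels = np.array(["a"] * 3 + ["b"] * 4)
            D = euclidean_dm(pts)
            robs = anosim_r_oracle(D.d, labels)
            perms = list(itertools.permutations(labels))
            exact = np.mean([anosim_r_oracle(D.d, np.array(p)) >= robs - 1e-12
                             for p in perms])
            res = anosim(D, GroupLabels(labels), n_perm=999, seed=trial)
            tol = 3 * np.sqrt(exact * (1 - exact) / 999) + 2 / 1000
            assert abs(res.p_value - exact) <= tol

    def test_R_bounded_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(4, 10))
            D = euclidean_dm(rng.normal(size=(n, 2)))
            labels = rng.choice(["a", "b"], size=n)
            if min((labels == "a").sum(), (labels == "b").sum()) < 2:
                continue
            res = anosim(D, GroupLabels(labels), n_perm=1, seed=0)
            assert -1 - 1e-12 <= res.R <= 1 + 1e-12

    def test_group_of_one_rejected(self):
        D = euclidean_dm([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValidationError, match="size"):
            anosim(D, GroupLabels(np.array(["a", "a", "b"])), n_perm=9, seed=0)

    def test_constant_matrix_R_zero_with_warning(self):
        D = euclidean_dm([[0, 0], [0, 0], [0, 0], [0, 0]])
        with pytest.warns(UserWarning, match="constant"):
            res = anosim(D, GroupLabels(np.array(["a", "a", "b", "b"])),
                         n_perm=9, seed=0)
        assert res.R == 0.0

    def test_p_value_formula(self):
        rng = np.random.default_rng(9)
        D = euclidean_dm(rng.normal(size=(8, 2)))
        res = anosim(D, GroupLabels(np.array(["a"] * 4 + ["b"] * 4)),
                     n_perm=99, seed=3)
        assert res.p_value == ((res.null_R >= res.R).sum() + 1) / (99 + 1)


class TestSimper:
    def test_identical_groups_zero_contributions(self):
        Y = np.tile([1.0, 2.0, 0.0], (6, 1))
        m = cm(Y)
        labels = GroupLabels(np.array(["a"] * 3 + ["b"] * 3))
        res = simper(m, labels, n_perm=9, seed=0)
        np.testing.assert_allclose(res.average, 0.0)

    def test_decomposition_identity_random(self):
        from dietpulse.experiments import simper_identity_residual

        assert simper_identity_residual(n_instances=30, seed=0) < 1e-10

    def test_hand_computed_pairs(self):
        # groups {u0,u1} vs {u2,u3}; contributions averaged over 4 pairs
        Y = np.array([[2.0, 0.0], [1.0, 1.0], [0.0, 2.0], [1.0, 3.0]])
        m = cm(Y)
        labels = GroupLabels(np.array(["a", "a", "b", "b"]))
        res = simper(m, labels, n_perm=9, seed=0)
        pairs = [(0, 2), (0, 3), (1, 2), (1, 3)]
        expect = np.zeros(2)
        for j, k in pairs:
            denom = Y[j].sum() + Y[k].sum()
            expect += np.abs(Y[j] - Y[k]) / denom
        expect /= len(pairs)
        np.testing.assert_allclose(res.average, expect, atol=1e-12)

    def test_more_than_two_groups_rejected(self):
        Y = np.ones((6, 2))
        m = cm(Y)
        with pytest.raises(ValidationError, match="pairwise"):
            simper(m, GroupLabels(np.array(["a", "a", "b", "b", "c", "c"])),
                   n_perm=9, seed=0)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        Y = rng.integers(0, 4, size=(10, 4)).astype(float)
        Y[Y.sum(axis=1) == 0, 0] = 1
        m = cm(Y)
        labels = GroupLabels(np.array(["a"] * 5 + ["b"] * 5))
        res = simper(m, labels, n_perm=99, seed=0, holm=True)
        assert (res.p_adjusted >= res.p_values - 1e-15).all()
        assert (res.p_adjusted <= 1.0).all()


class TestChiSquare:
    def test_proportional_rows_statistic_zero(self):
        ct = CountTable(pd.DataFrame([[10, 20], [20, 40]]))
        res = chi_square_independence(ct)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_three_by_four_df(self):
        rng = np.random.default_rng(0)
        ct = CountTable(pd.DataFrame(rng.integers(1, 20, size=(3, 4))))
        assert chi_square_independence(ct).df == 6

    def test_hand_value_2x2(self):
        ct = CountTable(pd.DataFrame([[10, 20], [20, 10]]))
        res = chi_square_independence(ct)
        assert res.statistic == pytest.approx(20 / 3)
        assert res.df == 1

    def test_expected_margins_match_observed(self):
        rng = np.random.default_rng(1)
        obs = rng.integers(1, 30, size=(3, 4))
        res = chi_square_independence(CountTable(pd.DataFrame(obs)))
        np.testing.assert_allclose(res.expected.sum(axis=1), obs.sum(axis=1),
                                   atol=1e-10)
        np.testing.assert_allclose(res.expected.sum(axis=0), obs.sum(axis=0),
                                   atol=1e-10)

    def test_zero_margin_rejected(self):
        ct = CountTable(pd.DataFrame([[0, 0], [3, 4]]))
        with pytest.raises(ValidationError, match="margin"):
            chi_square_independence(ct)
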