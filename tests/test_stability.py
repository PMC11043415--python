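import numpy as np
import pandas as pd
import pytest

from metstab import (
    ammi_fit,
    asi,
    asv,
    joint_regression,
    shukla_variance,
    stability_table,
    waas,
    waasy_ranking,
    wricke_ecovalence,
)
from metstab.exceptions import DegenerateInputError
from metstab.io import CellMeans

from conftest import random_means
from oracles import naive_ecovalence, naive_shukla, naive_waas


class TestASV:
    def test_equal_ss_and_null_second_score(self):
        # planted scores: one genotype lies entirely on axis 1
        Z = np.array(
            [[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.5, 0.5, -1.0], [-0.5, -0.5, 1.0]]
        )
        model = ammi_fit(CellMeans.from_matrix(Z))
        lam = model.singular_values_
        s = model.genotype_scores_
        vals = asv(model)
        w = lam[0] ** 2 / lam[1] ** 2
        for i in range(4):
            expected = np.hypot(w * s.iloc[i, 0], s.iloc[i, 1])
            assert vals.iloc[i] == pytest.approx(expected, rel=1e-9)

    def test_3x3_closed_form(self):
        """Direct formula evaluation from an independently computed SVD."""
        rng = np.random.default_rng(5)
        X = rng.normal(0, 4, (3, 3))
        model = ammi_fit(CellMeans.from_matrix(X))
        Z = model.interaction_.to_numpy()
        U, lam, Vt = np.linalg.svd(Z)
        s1 = np.abs(U[:, 0]) * np.sqrt(lam[0])  # |scores|: sign-free route
        s2 = np.abs(U[:, 1]) * np.sqrt(lam[1])
        expected = np.sqrt((lam[0] ** 2 / lam[1] ** 2 * s1) ** 2 + s2**2)
        np.testing.assert_allclose(asv(model).to_numpy(), expected, rtol=1e-7)

    def test_invariant_to_axis_sign_flips(self, rice_means, rice_ammi):
        flipped = ammi_fit(CellMeans.from_matrix(-rice_means.values))
        # negating the matrix flips every axis pair; ASV must not move
        np.testing.assert_allclose(
            asv(rice_ammi).to_numpy(), asv(flipped).to_numpy(), rtol=1e-9
        )

    def test_null_second_axis_falls_back(self):
        Z = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        model = ammi_fit(CellMeans.from_matrix(Z))
        with pytest.warns(RuntimeWarning, match="ASV"):
            vals = asv(model)
        np.testing.assert_allclose(
            vals.to_numpy(), np.abs(model.genotype_scores_["IPCA1"]), rtol=1e-12
        )


class TestASI:
    def test_weights_collapse_to_euclidean(self, rice_ammi):
        s = rice_ammi.genotype_scores_
        th1, th2 = rice_ammi.explained_interaction_[:2] / 100.0
        expected = np.sqrt((s["IPCA1"] * th1) ** 2 + (s["IPCA2"] * th2) ** 2)
        np.testing.assert_allclose(asi(rice_ammi).to_numpy(), expected.to_numpy())

    def test_zero_interaction_row(self):
        Z = np.array(
            [[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
        )
        model = ammi_fit(CellMeans.from_matrix(Z))
        vals = asi(model)
        assert vals.iloc[2] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_spreadsheet_recomputation(self, seed):
        means = random_means(seed, g=5, q=4)
        model = ammi_fit(means)
        Z = means.interaction().to_numpy()
        lam2 = np.sort(np.linalg.eigvalsh(Z @ Z.T))[::-1]
        th = lam2[:2] / lam2[lam2 > 1e-12].sum()
        U, lam, _ = np.linalg.svd(Z)
        s = np.abs(U[:, :2]) * np.sqrt(lam[:2])
        expected = np.sqrt((s[:, 0] * th[0]) ** 2 + (s[:, 1] * th[1]) ** 2)
        np.testing.assert_allclose(asi(model).to_numpy(), expected, rtol=1e-7)


class TestJointRegression:
    def test_constant_row_has_slope_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(10, 3, (4, 5))
        X[2] = 5.0
        b = joint_regression(CellMeans.from_matrix(X))
        assert b.iloc[2] == pytest.approx(0.0, abs=1e-12)

    def test_matches_ols_slope(self):
        """b_i equals the least-squares slope of the centered row on the index."""
        rng = np.random.default_rng(4)
        X = rng.normal(10, 3, (4, 5))
        b = joint_regression(CellMeans.from_matrix(X))
        I = X.mean(axis=0) - X.mean()
        for i in range(4):
            slope = np.polyfit(I, X[i] - X[i].mean(), 1)[0]
            assert b.iloc[i] == pytest.approx(slope, rel=1e-9)

    def test_additive_plus_index_rows(self):
        """A genotype whose row equals the index plus a constant has b=1."""
        I_shape = np.array([3.0, -2.0, 1.0, -2.0])
        X = np.vstack([I_shape + 10, I_shape + 12, I_shape + 8])
        b = joint_regression(CellMeans.from_matrix(X))
        np.testing.assert_allclose(b.to_numpy(), 1.0, atol=1e-12)

    def test_mean_slope_is_one(self, rice_means):
        assert joint_regression(rice_means).mean() == pytest.approx(1.0, abs=1e-9)

    def test_no_environmental_spread(self):
        X = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 4))
        with pytest.raises(DegenerateInputError):
            joint_regression(CellMeans.from_matrix(X))


class TestEcovalenceShukla:
    def test_additive_matrix_is_zero(self):
        X = 3.0 + np.arange(4.0)[:, None] + np.array([1.0, 5.0, 2.0])[None, :]
        np.testing.assert_allclose(
            wricke_ecovalence(CellMeans.from_matrix(X)), 0.0, atol=1e-18
        )

    def test_known_row(self):
        Z = np.array([[2.0, 0.0, -2.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 2.0]])
        w = wricke_ecovalence(CellMeans.from_matrix(Z))
        np.testing.assert_allclose(w.to_numpy(), [8.0, 0.0, 8.0])

    @pytest.mark.parametrize("seed", range(100))
    def test_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        g = int(rng.integers(3, 7))
        q = int(rng.integers(2, 7))
        X = rng.normal(50, 10, (g, q))
        means = CellMeans.from_matrix(X)
        w = wricke_ecovalence(means)
        np.testing.assert_allclose(w.to_numpy(), naive_ecovalence(X), rtol=1e-9)
        sig = shukla_variance(w, n_environments=q)
        np.testing.assert_allclose(
            sig.to_numpy(), naive_shukla(w.to_numpy(), g, q), rtol=1e-9
        )

    def test_sum_wi2_equals_interaction_ss(self, rice_means, rice_ammi):
        w = wricke_ecovalence(rice_means)
        assert w.sum() == pytest.approx(rice_ammi.interaction_ss_, rel=1e-6)

    def test_shukla_preserves_ecovalence_ranking(self, rice_means):
        w = wricke_ecovalence(rice_means)
        sig = shukla_variance(w, n_environments=rice_means.q)
        pd.testing.assert_series_equal(
            w.rank(), sig.rank(), check_names=False
        )

    def test_zero_ecovalence_gives_zero_shukla(self):
        w = pd.Series(np.zeros(5))
        np.testing.assert_allclose(shukla_variance(w, n_environments=4), 0.0)

    def test_too_few_genotypes(self):
        with pytest.raises(DegenerateInputError):
            shukla_variance(pd.Series([1.0, 2.0]), n_environments=4)


class TestWAAS:
    def test_single_axis_is_absolute_score(self, rice_ammi):
        vals = waas(rice_ammi, axes=1)
        np.testing.assert_allclose(
            vals.to_numpy(), rice_ammi.genotype_scores_["IPCA1"].abs().to_numpy()
        )

    def test_zero_interaction_genotype(self):
        Z = np.array(
            [[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]
        )
        model = ammi_fit(CellMeans.from_matrix(Z))
        assert waas(model).iloc[2] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(100))
    def test_hand_weighted_average(self, seed):
        means = random_means(seed, g=6, q=5)
        model = ammi_fit(means)
        expected = naive_waas(
            model.genotype_scores_.to_numpy(), model.explained_interaction_, 2
        )
        np.testing.assert_allclose(waas(model, axes=2).to_numpy(), expected, rtol=1e-9)


class TestWAASY:
    def test_pure_yield_weight_matches_mean_ranking(self, rice_means, rice_ammi):
        w = waas(rice_ammi)
        out = waasy_ranking(w, rice_means, weight_yield=100.0)
        by_score = out["WAASY"].rank(ascending=False)
        by_mean = rice_means.genotype_means.rank(ascending=False)
        pd.testing.assert_series_equal(by_score, by_mean, check_names=False)

    def test_pure_stability_weight_matches_waas_ranking(self, rice_means, rice_ammi):
        w = waas(rice_ammi)
        out = waasy_ranking(w, rice_means, weight_yield=0.0)
        by_score = out["WAASY"].rank(ascending=False)
        by_waas = w.rank(ascending=True)
        pd.testing.assert_series_equal(by_score, by_waas, check_names=False)

    def test_fifty_fifty_hand_computation(self):
        X = np.array([[10.0, 12.0, 8.0], [6.0, 7.0, 5.0], [9.0, 9.0, 9.0]])
        means = CellMeans.from_matrix(X)
        w = pd.Series([2.0, 0.0, 1.0], index=means.genotypes)
        out = waasy_ranking(w, means, weight_yield=50.0)
        # yield scores: G1=100, G2=0, G3=75; stability scores: G1=0, G2=100, G3=50
        np.testing.assert_allclose(out["WAASY"], [50.0, 50.0, 62.5])

    def test_degenerate_rescaling(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        means = CellMeans.from_matrix(X)
        w = pd.Series([1.0, 2.0, 3.0], index=means.genotypes)
        with pytest.raises(DegenerateInputError):
            waasy_ranking(w, means)

    def test_quadrant_classes(self, rice_means, rice_ammi):
        w = waas(rice_ammi)
        out = waasy_ranking(w, rice_means)
        grand = rice_means.grand_mean
        med = w.median()
        for gen, row in out.iterrows():
            prod = rice_means.genotype_means[gen] > grand
            stab = w[gen] < med
            expected = {
                (True, True): "productive-stable",
                (True, False): "productive-unstable",
                (False, True): "unproductive-stable",
                (False, False): "unproductive-unstable",
            }[(prod, stab)]
            assert row["quadrant"] == expected


class TestStabilityTable:
    def test_ranks_are_permutations(self, rice_means):
        table = stability_table(rice_means)
        g = rice_means.g
        for col in table.columns:
            if col.endswith("_rank"):
                assert sorted(table[col]) == pytest.approx(list(range(1, g + 1)))

    def test_nonnegative_statistics(self, rice_means):
        table = stability_table(rice_means)
        for col in ["ASV", "ASI", "Wi2", "WAAS"]:
            assert (table[col] >= 0).all()
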