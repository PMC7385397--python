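import numpy as np
import pandas as pd
import pytest

from droughtsel import markers as mk
from droughtsel.synthetic import MarkerMatrix
from conftest import marker_matrix_from_array
from oracles import fista_lasso, lasso_objective


class TestNormalizeMetabolites:
    def test_equal_analytes_map_to_zero(self):
        mm = marker_matrix_from_array(np.full((3, 4), 7.0))
        out = mk.normalize_metabolites(mm)
        assert np.allclose(out.values, 0.0)

    def test_direct_evaluation(self):
        mm = marker_matrix_from_array(np.array([[10.0, 1000.0]]))
        out = mk.normalize_metabolites(mm)
        assert out.values.iloc[0, 0] == pytest.approx(np.log10(10 / 505))
        assert out.values.iloc[0, 1] == pytest.approx(np.log10(1000 / 505))

    def test_per_sample_scale_invariance(self):
        x = np.abs(np.random.default_rng(0).lognormal(3, 1, (4, 6)))
        a = mk.normalize_metabolites(marker_matrix_from_array(x))
        b = mk.normalize_metabolites(marker_matrix_from_array(x * 10.0))
        assert np.allclose(a.values, b.values)

    def test_missing_cells_stay_missing(self):
        x = np.array([[1.0, 2.0, np.nan], [3.0, np.nan, 5.0]])
        out = mk.normalize_metabolites(marker_matrix_from_array(x))
        assert out.values.isna().sum().sum() == 2


class TestTranscriptExpression:
    def _ct(self, target_cts, ref_ct=20.0):
        x = np.column_stack([np.asarray(target_cts),
                             np.full(len(target_cts), ref_ct)])
        mm = marker_matrix_from_array(x, kind="transcript")
        mm.values.columns = ["geneA", "REF1"]
        return mm

    def test_target_equal_to_reference_gives_one(self):
        out = mk.transcript_expression(self._ct([20.0]), ["REF1"])
        assert out.values.iloc[0, 0] == pytest.approx(1.0)

    def test_one_cycle_above_reference_halves_expression(self):
        out = mk.transcript_expression(self._ct([21.0]), ["REF1"])
        assert out.values.iloc[0, 0] == pytest.approx(0.5)

    def test_per_sample_shift_invariance(self):
        a = mk.transcript_expression(self._ct([22.0], ref_ct=20.0), ["REF1"])
        b = mk.transcript_expression(self._ct([25.0], ref_ct=23.0), ["REF1"])
        assert np.allclose(a.values, b.values)

    def test_reference_columns_removed(self):
        out = mk.transcript_expression(self._ct([20.0]), ["REF1"])
        assert list(out.values.columns) == ["geneA"]


class TestImputeNipals:
    def test_complete_matrix_returned_unchanged(self):
        mm = marker_matrix_from_array(
            np.random.default_rng(1).normal(size=(10, 5)))
        out = mk.impute_nipals(mm)
        pd.testing.assert_frame_equal(out.values, mm.values)

    def test_rank_one_cell_recovered(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=12)
        p = rng.normal(size=6)
        x = np.outer(t, p)
        true_value = x[3, 2]
        x_miss = x.copy()
        x_miss[3, 2] = np.nan
        out = mk.impute_nipals(marker_matrix_from_array(x_miss),
                               n_components=1)
        assert out.values.iloc[3, 2] == pytest.approx(true_value, rel=1e-6)

    def test_observed_entries_untouched(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 8))
        x[rng.random(x.shape) < 0.1] = np.nan
        mm = marker_matrix_from_array(x)
        out = mk.impute_nipals(mm)
        obs = ~np.isnan(x)
        assert np.array_equal(out.values.to_numpy()[obs], x[obs])
        assert not out.values.isna().any().any()

    def test_beats_column_mean_imputation_on_low_rank_data(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=(100, 3))
        loads = rng.normal(size=(3, 30))
        x = scores @ loads + rng.normal(0, 0.1, (100, 30))
        mask = rng.random(x.shape) < 0.055
        x_miss = x.copy()
        x_miss[mask] = np.nan
        out = mk.impute_nipals(marker_matrix_from_array(x_miss),
                               n_components=3)
        err_nipals = np.mean((out.values.to_numpy()[mask] - x[mask]) ** 2)
        col_mean = np.nanmean(x_miss, axis=0)
        err_mean = np.mean((np.broadcast_to(col_mean, x.shape)[mask]
                            - x[mask]) ** 2)
        assert err_nipals < err_mean

    def test_excess_feature_missingness_rejected(self):
        x = np.random.default_rng(5).normal(size=(10, 3))
        x[:6, 0] = np.nan
        with pytest.raises(mk.MarkerError):
            mk.impute_nipals(marker_matrix_from_array(x))


class TestFitLassoCv:
    def test_noiseless_signal_recovered(self):
        rng = np.random.default_rng(6)
        n, p = 200, 51
        x = rng.normal(size=(n, p))
        y_vec = 2.0 * x[:, 0]
        mm = marker_matrix_from_array(x)
        y = {f"g{i}": float(y_vec[i]) for i in range(n)}
        model = mk.fit_lasso_cv(mm, y, seed=0)
        nz = model.coef[model.coef != 0]
        assert set(nz.index) <= {"f0"}
        assert model.coef["f0"] == pytest.approx(2.0, rel=0.1)

    def test_constant_response_gives_intercept_only(self):
        x = np.random.default_rng(7).normal(size=(30, 5))
        mm = marker_matrix_from_array(x)
        y = {f"g{i}": 0.7 for i in range(30)}
        with pytest.warns(RuntimeWarning):
            model = mk.fit_lasso_cv(mm, y, seed=0)
        assert model.n_nonzero == 0
        assert model.intercept == pytest.approx(0.7)

    def test_path_sparsity_monotone_in_lambda_orthogonal_design(self):
        """For orthogonal features the solution is soft-thresholding, so
        the active set can only grow as the penalty shrinks."""
        rng = np.random.default_rng(8)
        q, _ = np.linalg.qr(rng.normal(size=(60, 20)))
        x = q * np.sqrt(60)  # unit-variance orthogonal columns
        y_vec = x[:, :5] @ [1.0, -0.6, 0.4, 0.2, 0.1] + rng.normal(0, 0.5, 60)
        mm = marker_matrix_from_array(x)
        model = mk.fit_lasso_cv(mm, {f"g{i}": float(y_vec[i])
                                     for i in range(60)}, seed=1)
        # grid is descending in lambda -> nonzero counts non-decreasing
        assert (np.diff(model.nonzero_path) >= 0).all()

    def test_one_se_lambda_not_below_lambda_min(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(80, 15))
        y_vec = x[:, 0] + rng.normal(0, 1.0, 80)
        mm = marker_matrix_from_array(x)
        model = mk.fit_lasso_cv(mm, {f"g{i}": float(y_vec[i])
                                     for i in range(80)}, seed=2)
        assert model.lambda_1se >= model.lambda_min

    def test_coordinate_descent_matches_proximal_gradient(self):
        """Path solver objective agrees with an independent FISTA oracle."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            x = rng.normal(size=(20, 5))
            y = rng.normal(size=20)
            xs = (x - x.mean(0)) / x.std(0)
            yc = y - y.mean()
            lam_max = np.max(np.abs(xs.T @ yc)) / len(y)
            lambdas = lam_max * np.array([0.5, 0.1, 0.01])
            coefs = mk.l1_path(xs, yc, lambdas)
            for j, lam in enumerate(lambdas):
                w_oracle = fista_lasso(xs, yc, lam)
                obj_cd = lasso_objective(xs, yc, coefs[:, j], lam)
                obj_or = lasso_objective(xs, yc, w_oracle, lam)
                assert abs(obj_cd - obj_or) < 1e-8


class TestPredictDrym:
    def _model(self, coef, intercept=0.0, kind="metabolite"):
        features = list(coef.keys())
        return mk.LassoModel(
            intercept=intercept, coef=pd.Series(coef),
            lambda_grid=np.array([0.1]), cv_mean=np.array([0.0]),
            cv_se=np.array([0.0]), lambda_min=0.1, lambda_1se=0.1, kind=kind)

    def test_intercept_only_predicts_mean_with_tied_ranks(self):
        x = np.random.default_rng(11).normal(size=(6, 2))
        mm = marker_matrix_from_array(x)
        pred = mk.predict_drym(self._model({"f0": 0.0, "f1": 0.0},
                                           intercept=0.3), mm)
        assert np.allclose(pred["predicted_drym"], 0.3)
        assert np.allclose(pred["rank"], 3.5)

    def test_genotype_prediction_is_mean_of_sample_predictions(self):
        x = np.array([[1.0], [3.0], [10.0]])
        mm = marker_matrix_from_array(x, genotypes=["gA", "gA", "gB"])
        pred = mk.predict_drym(self._model({"f0": 1.0}), mm)
        by_geno = pred.set_index("genotype_id")["predicted_drym"]
        assert by_geno["gA"] == pytest.approx(2.0)
        assert by_geno["gB"] == pytest.approx(10.0)

    def test_missing_model_feature_rejected(self):
        mm = marker_matrix_from_array(np.ones((4, 1)))
        with pytest.raises(mk.MarkerError):
            mk.predict_drym(self._model({"f0": 1.0, "absent": 2.0}), mm)


class TestCombineRankings:
    def _table(self, ranks, preds=None, label="metabolite"):
        genos = [f"g{i}" for i in range(len(ranks))]
        return pd.DataFrame({
            "genotype_id": genos,
            "predicted_drym": preds if preds is not None
            else [-r for r in ranks],
            "rank": ranks, "model": label})

    def test_identical_rankings_preserved(self):
        a = self._table([1, 2, 3])
        b = self._table([1, 2, 3], label="transcript")
        out = mk.combine_rankings(a, b)
        assert list(out["genotype_id"]) == ["g0", "g1", "g2"]
        assert list(out["combined_score"]) == [1.0, 2.0, 3.0]

    def test_mean_of_rank_positions(self):
        a = self._table([1, 2, 3])
        b = self._table([3, 2, 1], label="transcript")
        out = mk.combine_rankings(a, b).set_index("genotype_id")
        assert out.loc["g0", "combined_score"] == 2.0
        assert np.allclose(out["combined_score"], 2.0)  # full reversal

    def test_disjoint_genotype_sets_rejected(self):
        a = self._table([1, 2, 3])
        b = self._table([1, 2, 3], label="transcript")
        b["genotype_id"] = ["h0", "h1", "h2"]
        with pytest.raises(mk.MarkerError):
            mk.combine_rankings(a, b)
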