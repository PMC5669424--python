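"""Tests of the model-fitting and comparison harness."""

import numpy as np
import pandas as pd
import pytest

from oracles import ols_normal_equations
from patcomplex import modeling, synthetic_ratings
from patcomplex.modeling import (
    ModelingError,
    aggregate_ratings,
    best_subset,
    fit_ols,
    lmm_compare,
    metrics,
    per_participant_models,
    rf_cv,
    zstandardize,
)


@pytest.fixture(scope="module")
def predictor_table():
    return synthetic_ratings.synthetic_predictor_table(n_stimuli=300, seed=42)


class TestAggregation:
    def test_single_and_pair_means(self):
        df = pd.DataFrame(
            {
                "participant": [1, 1, 2],
                "stimulus": ["a", "b", "b"],
                "rating": [4, 1, 5],
            }
        )
        means = aggregate_ratings(df)
        assert means["a"] == 4 and means["b"] == 3

    def test_excluded_repeat_ratings_do_not_enter_mean(self):
        df = pd.DataFrame(
            {
                "participant": [1, 2, 3],
                "stimulus": ["a", "a", "a"],
                "rating": [2, 4, 5],
                "excluded": [False, False, True],
            }
        )
        assert aggregate_ratings(df)["a"] == 3.0

    def test_empty_table_rejected(self):
        with pytest.raises(ModelingError):
            aggregate_ratings(pd.DataFrame(columns=["participant", "stimulus", "rating"]))


class TestStandardisation:
    def test_small_column_and_idempotence(self):
        z, params = zstandardize(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))
        assert list(z["x"]) == [-1.0, 0.0, 1.0]  # sample SD (ddof=1) is 1
        z2, _ = zstandardize(z)
        assert np.allclose(z2, z, atol=1e-12)

    def test_post_moments(self, predictor_table):
        z, _ = zstandardize(predictor_table)
        assert np.abs(z.mean()).max() < 1e-12
        assert np.abs(z.std(ddof=1) - 1).max() < 1e-12

    def test_constant_column_named_in_error(self):
        with pytest.raises(ModelingError, match="flat"):
            zstandardize(pd.DataFrame({"x": [1.0, 2.0], "flat": [3.0, 3.0]}))


class TestOLS:
    def test_exact_linear_response_gives_r2_one(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        y = 1.0 + 2.0 * X["a"] - 0.5 * X["b"]
        fit = fit_ols(X, y)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n, p = 40, 3
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(scale=0.5, size=n)
            fit = fit_ols(pd.DataFrame(X, columns=list("abc")), pd.Series(y))
            beta, se, r2 = ols_normal_equations(X, y)
            assert np.allclose(fit.params.to_numpy(), beta, atol=1e-10)
            assert np.allclose(fit.bse.to_numpy(), se, atol=1e-10)
            assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_rank_deficient_design_names_columns(self, rng):
        x = rng.normal(size=30)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ModelingError, match="collinear"):
            fit_ols(X, pd.Series(rng.normal(size=30)))

    def test_too_few_observations_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0], "b": [0.0, 1.0]})
        with pytest.raises(ModelingError):
            fit_ols(X, pd.Series([1.0, 2.0]))


class TestMetrics:
    def test_perfect_and_inverted_predictions(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert metrics(obs, obs) == pytest.approx((1, 1, 0, 0))
        r, *_ = metrics(-obs, obs)
        assert r == pytest.approx(-1.0)

    def test_worked_example_against_direct_formulas(self):
        pred, obs = np.array([1.0, 2.0, 3.0]), np.array([1.0, 2.0, 4.0])
        r, rs, rmse, mae = metrics(pred, obs)
        cov = np.mean((pred - pred.mean()) * (obs - obs.mean()))
        assert r == pytest.approx(cov / (pred.std() * obs.std()), abs=1e-12)
        assert rs == pytest.approx(1.0)  # ranks agree exactly
        assert rmse == pytest.approx(np.sqrt(1 / 3))
        assert mae == pytest.approx(1 / 3)

    def test_constant_input_rejected(self):
        with pytest.raises(ModelingError):
            metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBestSubset:
    def test_response_equal_to_one_predictor_wins(self, predictor_table):
        y = predictor_table["CANMN"].copy()
        result = best_subset(predictor_table, y, k_max=2)
        assert result[1][0].predictors == ("CANMN",)
        assert result[1][0].r_squared == pytest.approx(1.0, abs=1e-10)

    def test_r2_monotone_in_subset_size(self, predictor_table, rng):
        y = pd.Series(
            0.5 * predictor_table["RMSGIF"] - 0.4 * predictor_table["MS"]
            + rng.normal(size=len(predictor_table)),
            index=predictor_table.index,
        )
        result = best_subset(predictor_table, y, k_max=3)
        assert result[1][0].r_squared <= result[2][0].r_squared <= result[3][0].r_squared

    def test_deterministic_ranking(self, predictor_table, rng):
        y = pd.Series(rng.normal(size=len(predictor_table)), index=predictor_table.index)
        a = best_subset(predictor_table, y, k_max=2)
        b = best_subset(predictor_table, y, k_max=2)
        assert [m.predictors for m in a[2]] == [m.predictors for m in b[2]]

    def test_too_many_predictors_rejected(self, rng):
        wide = pd.DataFrame(rng.normal(size=(40, 31)))
        with pytest.raises(ModelingError):
            best_subset(wide, pd.Series(rng.normal(size=40)), k_max=1)


class TestRandomForestCV:
    def test_seeded_determinism(self, predictor_table, rng):
        y = pd.Series(rng.normal(size=len(predictor_table)), index=predictor_table.index)
        a = rf_cv(predictor_table, ("MS", "RMSGIF"), y, seed=5, n_estimators=50)
        b = rf_cv(predictor_table, ("MS", "RMSGIF"), y, seed=5, n_estimators=50)
        assert a.predictions.equals(b.predictions)
        assert a.r_squared == b.r_squared

    def test_out_of_fold_predictions_form_partition(self, predictor_table, rng):
        y = pd.Series(rng.normal(size=len(predictor_table)), index=predictor_table.index)
        res = rf_cv(predictor_table, ("MS",), y, folds=10, seed=1, n_estimators=20)
        assert res.predictions.index.equals(predictor_table.index)
        assert not res.predictions.isna().any()

    def test_noiseless_monotone_function_is_learned(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-2, 2, 500)
        table = pd.DataFrame({"x": x})
        y = pd.Series(np.tanh(2 * x) + 0.2 * x)
        res = rf_cv(table, ("x",), y, folds=10, seed=3)
        assert res.r_squared > 0.9

    def test_invalid_inputs_rejected(self, predictor_table):
        y = pd.Series(1.0, index=predictor_table.index)
        with pytest.raises(ModelingError):
            rf_cv(predictor_table, (), y)
        with pytest.raises(ModelingError):
            rf_cv(predictor_table.head(5), ("MS",), y.head(5), folds=10)


class TestPerParticipant:
    def test_identical_participants_recover_group_model(self, predictor_table, rng):
        z, _ = zstandardize(predictor_table)
        latent = 3 + 0.6 * z["RMSGIF"] - 0.5 * z["MS"] + 0.1 * rng.normal(size=len(z))
        shared = np.clip(np.rint(latent), 1, 5).astype(int)
        frames = [
            pd.DataFrame({"participant": p, "stimulus": z.index, "rating": shared})
            for p in range(1, 6)
        ]
        ratings = pd.concat(frames, ignore_index=True)
        res = per_participant_models(ratings, predictor_table)
        assert len(res.models) == 5
        group_best = best_subset(z, aggregate_ratings(ratings), k_max=2)[2][0].predictors
        for m in res.models:
            assert tuple(sorted(m.best_predictors)) == tuple(sorted(group_best))
            assert m.delta_r_squared >= -1e-12

    def test_heterogeneous_weights_concentrate_counts(self, predictor_table):
        spec = synthetic_ratings.RatingSimSpec(
            slope_sd_quant=0.15, slope_sd_sym=0.15, noise_sd=0.4,
            n_participants=12, seed=9,
        )
        ratings, _ = synthetic_ratings.simulate_ratings(predictor_table, spec)
        res = per_participant_models(ratings, predictor_table)
        top = [name for name, _ in res.predictor_counts.most_common(2)]
        assert set(top) == {"MS", "RMSGIF"}
        assert res.n_within(0.05) >= len(res.models) - 2

    def test_constant_raters_flagged(self, predictor_table):
        ratings = pd.DataFrame(
            {
                "participant": 1,
                "stimulus": predictor_table.index[:30],
                "rating": 3,
            }
        )
        res = per_participant_models(ratings, predictor_table)
        assert res.excluded_participants == [1]
        assert res.models == []


@pytest.fixture(scope="module")
def lmm_table():
    return synthetic_ratings.synthetic_predictor_table(n_stimuli=80, seed=3)


class TestLmmCompare:
    @pytest.fixture
    def table(self, lmm_table):
        return lmm_table

    def test_nested_deviances_monotone(self, table):
        spec = synthetic_ratings.RatingSimSpec(
            slope_sd_quant=0.2, slope_sd_sym=0.2, n_participants=25, seed=4
        )
        ratings, _ = synthetic_ratings.simulate_ratings(table, spec)
        res = lmm_compare(ratings, table)
        llf = {f.name: f.llf for f in res.fits}
        assert llf["M2"] >= llf["M1"] - 1e-6
        assert llf["M3"] >= llf["M1"] - 1e-6
        assert llf["M4"] >= max(llf["M2"], llf["M3"]) - 1e-6

    def test_true_slopes_detected_and_m4_preferred(self, table):
        spec = synthetic_ratings.RatingSimSpec(
            slope_sd_quant=0.25, slope_sd_sym=0.25, n_participants=30, seed=11
        )
        ratings, _ = synthetic_ratings.simulate_ratings(table, spec)
        res = lmm_compare(ratings, table)
        assert res.lrt_pvalues["MS"] < 0.05
        assert res.lrt_pvalues["RMSGIF"] < 0.05
        assert res.aic_ranking[0] == "M4"
        m4 = next(f for f in res.fits if f.name == "M4")
        assert all(v >= 0 for v in m4.slope_vars.values())
        # fixed effects keep the two-factor signs
        assert m4.fe_params["RMSGIF"] > 0 > m4.fe_params["MS"]

    def test_zero_slopes_yield_small_variances(self, table):
        spec = synthetic_ratings.RatingSimSpec(n_participants=30, seed=2)
        ratings, _ = synthetic_ratings.simulate_ratings(table, spec)
        res = lmm_compare(ratings, table)
        m4 = next(f for f in res.fits if f.name == "M4")
        assert all(v < 0.01 for v in m4.slope_vars.values())

    def test_missing_predictor_rejected(self, table):
        ratings = pd.DataFrame(
            {"participant": [1], "stimulus": [table.index[0]], "rating": [3]}
        )
        with pytest.raises(ModelingError):
            lmm_compare(ratings, table, predictors=("MS", "NOPE"))
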