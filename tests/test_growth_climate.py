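import numpy as np
import pandas as pd
import pytest

import fishclim as fc
from fishclim.exceptions import DegenerateDataError, InvalidArgumentError
from fishclim.growth_climate import (
    GrowthClimateModel,
    GrowthEnsemble,
    assess_rmse,
    build_growth_ensemble,
    compute_gcv,
    fit_growth_family,
    loo_mse_hat,
    loo_mse_refit,
    project_growth,
)


def linear_table(n=30, slope=-10.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(6, 13, n)
    df = pd.DataFrame(
        {
            "population_id": [f"p{i}" for i in range(n)],
            "annual_mean_temp": t,
            "annual_precip": rng.uniform(700, 1200, n),
            "Linf_mm": 420.0 + slope * t + rng.normal(0, noise, n),
        }
    )
    return df


VARS = ["annual_mean_temp", "annual_precip"]


class TestFitGrowthFamily:
    def test_glm_reproduces_nested_linear_truth(self):
        table = linear_table(noise=0.0)
        model = fit_growth_family(table, "Linf_mm", "GLM", VARS)
        pred = model.predict_table(table)
        np.testing.assert_allclose(pred, table["Linf_mm"], rtol=1e-10)
        assert model.gcv < 1e-10

    @pytest.mark.parametrize("family", ["GLM", "MARS"])
    def test_constant_target_predicted_constant(self, family):
        table = linear_table(slope=0.0, noise=0.0)
        table["Linf_mm"] = 300.0
        model = fit_growth_family(table, "Linf_mm", family, VARS)
        np.testing.assert_allclose(model.predict_table(table), 300.0, atol=1e-8)

    def test_glm_slope_within_sampling_error(self):
        table = linear_table(n=100, slope=-10.0, noise=8.0, seed=5)
        model = fit_growth_family(table, "Linf_mm", "GLM", VARS)
        coef_t = model.meta["params"][1]  # intercept, temp, precip
        X = table["annual_mean_temp"]
        se = 8.0 / np.sqrt(np.sum((X - X.mean()) ** 2))
        assert abs(coef_t - (-10.0)) < 2.5 * se

    def test_gam_fits_and_reports_finite_gcv(self):
        table = linear_table(n=40, noise=5.0, seed=2)
        model = fit_growth_family(table, "Linf_mm", "GAM", VARS)
        assert np.isfinite(model.gcv) and model.gcv >= 0
        assert model.meta["degree"] in (2, 3)

    def test_mars_honours_linear_signal(self):
        table = linear_table(n=60, slope=-10.0, noise=2.0, seed=3)
        model = fit_growth_family(table, "Linf_mm", "MARS", VARS)
        rmse = np.sqrt(np.mean((model.predict_table(table) - table["Linf_mm"]) ** 2))
        assert rmse < 10.0

    def test_too_few_populations(self):
        with pytest.raises(DegenerateDataError):
            fit_growth_family(linear_table(n=5), "Linf_mm", "GLM", VARS)


class TestComputeGCV:
    def test_hand_loo_on_four_points(self):
        # brute-force LOO oracle: four explicit refits of y ~ x
        table = pd.DataFrame(
            {
                "population_id": list("abcd"),
                "x": [1.0, 2.0, 3.0, 4.0],
                "Linf_mm": [2.0, 2.9, 4.2, 4.9],
            }
        )
        model = fit_growth_family(table, "Linf_mm", "GLM", ["x"], min_populations=4)
        x = table["x"].to_numpy()
        y = table["Linf_mm"].to_numpy()
        preds = []
        for i in range(4):
            mask = np.arange(4) != i
            b, a = np.polyfit(x[mask], y[mask], 1)
            preds.append(a + b * x[i])
        oracle = np.mean((y - np.array(preds)) ** 2)
        assert compute_gcv(model, table) == pytest.approx(oracle, abs=1e-12)

    def test_closed_form_equals_explicit_refits_for_glm(self):
        rng = np.random.default_rng(7)
        for n in (10, 25, 50):
            table = linear_table(n=n, noise=6.0, seed=int(rng.integers(1e6)))
            model = fit_growth_family(table, "Linf_mm", "GLM", VARS)
            X = table[VARS].to_numpy()
            y = table["Linf_mm"].to_numpy()
            assert loo_mse_hat(X, y) == pytest.approx(
                loo_mse_refit(model, X, y), abs=1e-8
            )

    def test_noiseless_linear_gcv_tiny(self):
        model_table = linear_table(noise=0.0)
        model = fit_growth_family(model_table, "Linf_mm", "GLM", VARS)
        assert compute_gcv(model, model_table) < 1e-10


def fake_model(gcv, offset=0.0, target="Linf_mm"):
    return GrowthClimateModel(
        target=target,
        family=f"F{gcv}_{offset}",
        climate_vars=["annual_mean_temp"],
        predict=lambda X: np.full(len(X), offset),
        refit=lambda X, y: (lambda Xn: np.full(len(Xn), offset)),
        gcv=gcv,
    )


class TestBuildGrowthEnsemble:
    def test_single_member(self):
        ens = build_growth_ensemble([fake_model(2.0)])
        assert [w for _, w in ens.members] == [1.0]

    def test_equal_gcvs_split_evenly(self):
        ens = build_growth_ensemble([fake_model(2.0), fake_model(2.0, 1.0)])
        assert [w for _, w in ens.members] == [pytest.approx(0.5)] * 2

    def test_inverse_gcv_weighting(self):
        ens = build_growth_ensemble([fake_model(1.0), fake_model(3.0, 1.0)])
        weights = [w for _, w in ens.members]
        assert weights[0] == pytest.approx(0.75)
        assert weights[1] == pytest.approx(0.25)
        # weight ordering is inverse to gcv ordering
        assert weights[0] > weights[1]

    def test_zero_gcv_member_takes_all(self):
        ens = build_growth_ensemble([fake_model(0.0), fake_model(2.0, 1.0)])
        assert dict(ens.members) == {"F0.0_0.0": 1.0}
        tie = build_growth_ensemble([fake_model(0.0), fake_model(0.0, 1.0)])
        assert sorted(w for _, w in tie.members) == [0.5, 0.5]

    def test_no_valid_member(self):
        with pytest.raises(InvalidArgumentError):
            build_growth_ensemble([])

    def test_weights_sum_to_one(self):
        ens = build_growth_ensemble(
            [fake_model(g, i) for i, g in enumerate((0.5, 1.5, 4.0))]
        )
        assert abs(sum(w for _, w in ens.members) - 1.0) < 1e-12


class TestAssessRMSE:
    def _ens_with_residuals(self, y, residuals):
        table = pd.DataFrame(
            {
                "population_id": [f"p{i}" for i in range(len(y))],
                "annual_mean_temp": np.arange(len(y), dtype=float),
                "Linf_mm": y,
            }
        )
        pred = np.asarray(y) + np.asarray(residuals)
        model = GrowthClimateModel(
            target="Linf_mm",
            family="GLM",
            climate_vars=["annual_mean_temp"],
            predict=lambda X: pred[: len(X)],
            refit=None,
            gcv=1.0,
        )
        ens = GrowthEnsemble("Linf_mm", [("GLM", 1.0)], {"GLM": model})
        return ens, table

    def test_perfect_predictions(self):
        ens, table = self._ens_with_residuals([300.0, 310.0], [0.0, 0.0])
        assert assess_rmse(ens, table) == 0.0

    def test_unit_residuals(self):
        ens, table = self._ens_with_residuals([300.0, 310.0], [1.0, -1.0])
        assert assess_rmse(ens, table) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        ens, table = self._ens_with_residuals([300.0, 310.0], [3.0, 4.0])
        assert assess_rmse(ens, table) == pytest.approx(np.sqrt(12.5))


class TestProjectGrowth:
    def _setup(self, growth_table):
        table = growth_table["table"]
        vars_ = list(fc.grid.CORE_VARIABLES)
        ens_l = fc.fit_growth_ensemble(table, "Linf_mm", vars_, families=("GLM",))
        ens_k = fc.fit_growth_ensemble(table, "K_per_yr", vars_, families=("GLM",))
        pops = table[["population_id", "cell_id"]]
        return table, ens_l, ens_k, pops

    def test_identity_scenario_returns_baseline_fits(self, growth_table):
        table, ens_l, ens_k, pops = self._setup(growth_table)
        proj = project_growth(ens_l, ens_k, growth_table["grid"], pops)
        np.testing.assert_allclose(
            proj.per_population["Linf_hat_mm"], ens_l.predict_table(table)
        )
        assert proj.ci_Linf[0] < proj.mean_Linf < proj.ci_Linf[1]
        assert proj.n_valid == len(pops)

    def test_pure_glm_warming_shift_is_linear(self, growth_table):
        table, ens_l, ens_k, pops = self._setup(growth_table)
        grid = growth_table["grid"]
        warmed = fc.apply_scenario(grid, fc.ScenarioSpec("w2", 2.0, 1.0))
        base = project_growth(ens_l, ens_k, grid, pops)
        warm = project_growth(ens_l, ens_k, warmed, pops)
        glm = ens_l.models["GLM"]
        # per-variable coefficients: temp-type variables all shift by +2
        params = glm.meta["params"][1:]
        shifted_vars = [
            v for v in fc.grid.TEMPERATURE_VARIABLES if v in glm.climate_vars
        ]
        expected = 2.0 * sum(
            params[glm.climate_vars.index(v)] for v in shifted_vars
        )
        observed = (
            warm.per_population["Linf_hat_mm"] - base.per_population["Linf_hat_mm"]
        )
        np.testing.assert_allclose(observed, expected, rtol=1e-8)

    def test_single_population_ci_degenerate(self, growth_table):
        table, ens_l, ens_k, pops = self._setup(growth_table)
        with pytest.warns(UserWarning, match="single population"):
            proj = project_growth(
                ens_l, ens_k, growth_table["grid"], pops.iloc[:1]
            )
        assert np.isnan(proj.se_Linf)
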