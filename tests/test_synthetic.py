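import numpy as np
import pytest

import fishclim as fc
from fishclim.exceptions import InvalidArgumentError, SchemaError


def pearson_r(x, y):
    """Direct Pearson correlation by its definition (independent oracle)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


class TestClimateGrid:
    def test_size_contract(self):
        g = fc.generate_climate_grid(2, 2, seed=1)
        assert g.n_cells == 4
        assert len(g.variables) >= 6
        assert np.isfinite(g.values()).all()

    def test_seed_determinism_is_byte_identical(self):
        a = fc.generate_climate_grid(20, 30, seed=7)
        b = fc.generate_climate_grid(20, 30, seed=7)
        assert a.data.to_csv() == b.data.to_csv()

    def test_temperature_declines_with_latitude(self):
        g = fc.generate_climate_grid(20, 30, seed=7)
        r = pearson_r(g.data["annual_mean_temp"], g.data["lat"])
        assert r < -0.8

    def test_a_redundant_variable_pair_exists(self):
        g = fc.generate_climate_grid(20, 30, seed=7)
        r = pearson_r(
            g.data["annual_mean_temp"], g.data["max_temp_warmest_month"]
        )
        assert abs(r) > 0.70

    def test_rejects_degenerate_dimensions(self):
        with pytest.raises(InvalidArgumentError):
            fc.generate_climate_grid(1, 5, seed=0)


class TestOccurrences:
    def test_neutral_niche_prevalence_near_half(self):
        g = fc.generate_climate_grid(100, 100, seed=2)
        occ = fc.generate_occurrences(
            g, fc.NicheSpec(intercept=0.0, coefficients={}), seed=3
        )
        # Binomial(10000, 0.5): mean within ±3 sd of 0.5
        assert 0.47 <= occ.prevalence <= 0.53

    def test_saturated_niche_gives_all_presences(self, small_grid):
        occ = fc.generate_occurrences(
            small_grid,
            fc.NicheSpec(intercept=50.0, coefficients={}),
            seed=1,
        )
        assert occ.records["presence"].eq(1).all()

    def test_prevalence_target_rescues_saturated_niche(self, small_grid):
        occ = fc.generate_occurrences(
            small_grid,
            fc.NicheSpec(
                intercept=50.0, coefficients={}, prevalence_target=0.4
            ),
            seed=1,
        )
        assert 0 < occ.prevalence < 1

    def test_warm_niche_occupies_warm_cells(self, small_grid):
        occ = fc.generate_occurrences(
            small_grid,
            fc.NicheSpec(
                intercept=-12.0,
                coefficients={"annual_mean_temp": 1.3},
                prevalence_target=0.4,
            ),
            seed=4,
        )
        merged = occ.records.merge(small_grid.data, on="cell_id")
        t_pres = merged.loc[merged.presence == 1, "annual_mean_temp"].mean()
        t_abs = merged.loc[merged.presence == 0, "annual_mean_temp"].mean()
        assert t_pres > t_abs

    def test_unknown_niche_variable_is_a_schema_error(self, small_grid):
        with pytest.raises(SchemaError):
            fc.generate_occurrences(
                small_grid, fc.NicheSpec(0.0, {"no_such_var": 1.0}), seed=0
            )


class TestGrowthData:
    def _resp(self, **kw):
        base = dict(
            Linf_intercept=420.0,
            Linf_temp_slope=-12.0,
            K_intercept=0.06,
            K_temp_slope=0.02,
            scale_intercept=0.5,
            scale_slope=0.01,
        )
        base.update(kw)
        return fc.GrowthResponseSpec(**base)

    def test_noise_free_capture_lengths_are_exact(self, small_grid):
        cells = list(small_grid.data["cell_id"][:3])
        obs, truth = fc.generate_growth_data(
            small_grid, cells, 20, 8, self._resp(), seed=1
        )
        merged = obs.merge(truth, on="population_id")
        expected = fc.vbgf_length(
            merged["Linf_true"], merged["K_true"], merged["age_capture"]
        )
        np.testing.assert_allclose(merged["capture_length_mm"], expected)
        # scale radii likewise exact, and annulus radius never exceeds capture
        assert (obs["scale_radius_annulus"] <= obs["scale_radius_capture"]).all()

    def test_linf_difference_tracks_temperature_linearly(self):
        # two cells 3 degC apart, no noise: true Linf differs by exactly 30 mm
        import pandas as pd

        data = pd.DataFrame(
            {
                "cell_id": ["a", "b"],
                "lon": [0.0, 0.0],
                "lat": [50.0, 51.0],
                "annual_mean_temp": [10.0, 7.0],
                "annual_precip": [900.0, 900.0],
            }
        )
        grid = fc.ClimateGrid(data)
        _, truth = fc.generate_growth_data(
            grid, ["a", "b"], 5, 5, self._resp(Linf_temp_slope=-10.0), seed=2
        )
        diff = truth["Linf_true"].iloc[1] - truth["Linf_true"].iloc[0]
        assert diff == pytest.approx(30.0)

    def test_population_mean_linf_matches_linear_predictor(self, small_grid):
        # 200 populations on one cell: mean of true Linf within 2 SE
        cells = [small_grid.data["cell_id"].iloc[0]] * 200
        resp = self._resp(sd_Linf=20.0)
        _, truth = fc.generate_growth_data(small_grid, cells, 1, 5, resp, seed=8)
        t = truth["temperature"].iloc[0]
        predicted = resp.Linf_intercept + resp.Linf_temp_slope * t
        se = 20.0 / np.sqrt(200)
        assert abs(truth["Linf_true"].mean() - predicted) < 2 * se

    def test_nonpositive_growth_parameters_rejected(self, small_grid):
        cells = list(small_grid.data["cell_id"][:2])
        with pytest.raises(InvalidArgumentError):
            fc.generate_growth_data(
                small_grid, cells, 5, 5, self._resp(Linf_temp_slope=-100.0), seed=1
            )

    def test_seed_determinism(self, small_grid):
        cells = list(small_grid.data["cell_id"][:3])
        a, _ = fc.generate_growth_data(small_grid, cells, 10, 8, self._resp(), seed=5)
        b, _ = fc.generate_growth_data(small_grid, cells, 10, 8, self._resp(), seed=5)
        assert a.to_csv() == b.to_csv()


def test_noise_free_generator_to_fit_round_trip(small_grid):
    """End-to-end link: noise-free synthetic growth data refit exactly."""
    resp = fc.GrowthResponseSpec(
        Linf_intercept=420.0,
        Linf_temp_slope=-12.0,
        K_intercept=0.06,
        K_temp_slope=0.02,
        scale_intercept=0.5,
        scale_slope=0.01,
    )
    cells = list(small_grid.data["cell_id"][::7][:8])
    obs, truth = fc.generate_growth_data(small_grid, cells, 25, 10, resp, seed=6)
    fitted = fc.fit_populations(obs).merge(truth, on="population_id")
    np.testing.assert_allclose(fitted["Linf_mm"], fitted["Linf_true"], rtol=1e-4)
    np.testing.assert_allclose(fitted["K_per_yr"], fitted["K_true"], rtol=1e-4)
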