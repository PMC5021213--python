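import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import fishclim as fc

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    """A 10×12 Britain-like baseline grid."""
    return fc.generate_climate_grid(10, 12, seed=11)


@pytest.fixture(scope="session")
def separable_occurrences(small_grid):
    """A strongly temperature-driven species on the small grid."""
    niche = fc.NicheSpec(
        intercept=-12.0,
        coefficients={"annual_mean_temp": 1.3},
        prevalence_target=0.4,
    )
    return fc.generate_occurrences(small_grid, niche, seed=5)


@pytest.fixture(scope="session")
def growth_table():
    """Per-population growth parameters joined to baseline climate (n=40)."""
    grid = fc.generate_climate_grid(12, 14, seed=23)
    resp = fc.GrowthResponseSpec(
        Linf_intercept=420.0,
        Linf_temp_slope=-12.0,
        K_intercept=0.06,
        K_temp_slope=0.02,
        sd_Linf=15.0,
        sd_K=0.02,
        length_cv=0.05,
        scale_intercept=0.5,
        scale_slope=0.01,
        scale_sd=0.05,
    )
    rng = np.random.default_rng(3)
    cells = rng.choice(grid.data["cell_id"].to_numpy(), size=40, replace=False)
    obs, truth = fc.generate_growth_data(grid, list(cells), 40, 10, resp, seed=9)
    params = fc.fit_populations(obs)
    table = params.merge(
        grid.data[["cell_id", *fc.grid.CORE_VARIABLES]], on="cell_id"
    )
    return {"grid": grid, "table": table, "truth": truth, "resp": resp}


@pytest.fixture(scope="session")
def demo_run():
    """One full default demonstration pipeline run (shared across tests)."""
    from fishclim.pipeline import demo_config, run_pipeline

    return run_pipeline(demo_config(seed=1))


def make_presence_grid(probs: dict, threshold: float = 0.6, species="sp", scen="s"):
    return fc.PresenceGrid(
        species=species,
        scenario_name=scen,
        cell_probabilities=pd.Series(probs),
        threshold=threshold,
    )
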