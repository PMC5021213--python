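"""Synthetic study-system generator.

Emulates the three data streams the coupled range/growth analysis consumes:

* a gridded climate baseline with a latitudinal temperature gradient,
  west–east continentality, and correlated auxiliary variables (so that
  correlation-based variable reduction has something to remove);
* presence/absence records drawn from a logistic climate niche;
* per-fish length-at-age observations with scale radii, in which asymptotic
  length L∞ declines and growth coefficient K rises with temperature — the
  temperature–size-rule structure the analysis is designed to detect.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import derive_rng
from .exceptions import DegenerateDataError, InvalidArgumentError, SchemaError
from .grid import ClimateGrid, recompute_isothermality
from .growth import vbgf_length
from .sdm import OccurrenceSet


@dataclass(frozen=True)
class NicheSpec:
    """Logistic climate niche: P(presence) = expit(intercept + Σ coef·x)."""

    intercept: float
    coefficients: Mapping[str, float]
    prevalence_target: float | None = None

    def __post_init__(self) -> None:
        if self.prevalence_target is not None and not (
            0.0 < self.prevalence_target < 1.0
        ):
            raise InvalidArgumentError("prevalence_target must lie in (0, 1)")


@dataclass(frozen=True)
class GrowthResponseSpec:
    """Linear temperature responses of the von Bertalanffy parameters.

    ``Linf = Linf_intercept + Linf_temp_slope · T + N(0, sd_Linf)`` (mm) and
    ``K = K_intercept + K_temp_slope · T + N(0, sd_K)`` (yr⁻¹), with
    ``Linf_temp_slope`` expected negative and ``K_temp_slope`` positive under
    the temperature–size rule. ``length_cv`` is the coefficient of variation
    of multiplicative (lognormal) length noise; the ``scale_*`` fields give
    the linear scale-radius–body-length relation and its Gaussian noise.
    """

    Linf_intercept: float
    Linf_temp_slope: float
    K_intercept: float
    K_temp_slope: float
    sd_Linf: float = 0.0
    sd_K: float = 0.0
    length_cv: float = 0.0
    scale_intercept: float = 0.0
    scale_slope: float = 0.01
    scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.K_intercept <= 0:
            raise InvalidArgumentError("K_intercept must be positive")
        for name in ("sd_Linf", "sd_K", "length_cv", "scale_sd"):
            if getattr(self, name) < 0:
                raise InvalidArgumentError(f"{name} must be non-negative")
        if self.scale_slope <= 0:
            raise InvalidArgumentError("scale_slope must be positive")


class GrowthDataset(NamedTuple):
    """Observations plus the generating per-population truth (for checking)."""

    observations: pd.DataFrame
    true_params: pd.DataFrame


def generate_climate_grid(
    n_lon: int,
    n_lat: int,
    seed: int,
    lon_range: tuple[float, float] = (-6.0, 2.0),
    lat_range: tuple[float, float] = (50.0, 59.0),
) -> ClimateGrid:
    """Generate a Britain-like baseline climate grid.

    One cell per (lon, lat) node of a regular ``n_lon × n_lat`` grid. Annual
    mean temperature declines with latitude (≈ −0.65 °C per degree north) and
    rises gently eastward; continentality (annual temperature range) grows
    eastward; precipitation is higher in the north-west. The warmest-month
    maximum and coldest-month minimum track annual mean temperature with
    |r| > 0.7, providing the redundant variables that correlation-based
    reduction is meant to discard. Isothermality satisfies
    ``100 · diurnal_range / annual_temp_range`` exactly on every cell.
    """
    if n_lon < 2 or n_lat < 2:
        raise InvalidArgumentError("n_lon and n_lat must both be >= 2")
    rng = derive_rng(seed, "climate_grid")
    lons = np.linspace(*lon_range, n_lon)
    lats = np.linspace(*lat_range, n_lat)
    lon, lat = [a.ravel() for a in np.meshgrid(lons, lats)]
    n = lon.size

    t_ann = 9.5 - 0.65 * (lat - 54.5) + 0.15 * (lon + 2.0) + rng.normal(0, 0.35, n)
    diurnal = 7.5 + 0.10 * (lon + 2.0) + rng.normal(0, 0.30, n)
    # Continentality grows eastward; both extremes shift with annual mean.
    t_min = t_ann - (7.0 + 0.8 * (lon + 6.0)) + rng.normal(0, 0.25, n)
    t_max = t_ann + (11.0 + 0.4 * (lon + 6.0)) + rng.normal(0, 0.25, n)
    t_wet = t_ann - 2.5 - 0.3 * (lon + 2.0) + rng.normal(0, 2.2, n)
    t_dry = t_ann + 4.0 + 0.3 * (lon + 2.0) + rng.normal(0, 2.2, n)
    precip = 1000.0 + 15.0 * (lat - 54.5) - 25.0 * (lon + 2.0) + rng.normal(0, 80.0, n)

    data = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n)],
            "lon": lon,
            "lat": lat,
            "annual_mean_temp": t_ann,
            "diurnal_range": diurnal,
            "isothermality": np.nan,
            "temp_wettest_quarter": t_wet,
            "temp_driest_quarter": t_dry,
            "annual_precip": precip,
            "max_temp_warmest_month": t_max,
            "min_temp_coldest_month": t_min,
            "annual_temp_range": t_max - t_min,
        }
    )
    recompute_isothermality(data)
    return ClimateGrid(data, scenario_name="baseline")


def generate_occurrences(
    grid: ClimateGrid,
    niche: NicheSpec,
    seed: int,
    species: str = "synthetic_species",
    max_retries: int = 5,
) -> OccurrenceSet:
    """Draw presence/absence from the logistic niche, cell by cell.

    With a ``prevalence_target``, a draw that leaves one class empty
    re-centres the intercept toward that target prevalence and redraws;
    persistent degeneracy raises
    :class:`~fishclim.exceptions.DegenerateDataError`. Without a target the
    draw is returned as-is — a saturated niche yields an (unusable for
    modelling, but faithful) one-class set.
    """
    unknown = [v for v in niche.coefficients if v not in grid.variables]
    if unknown:
        raise SchemaError(f"niche references unknown variables {unknown}")
    variables = list(niche.coefficients)
    X = grid.values(variables)
    coef = np.array([niche.coefficients[v] for v in variables], dtype=float)
    linpred = X @ coef
    intercept = float(niche.intercept)
    rng = derive_rng(seed, "occurrences", species)
    for attempt in range(max_retries + 1):
        p = expit(intercept + linpred)
        presence = (rng.random(len(p)) < p).astype(int)
        records = pd.DataFrame(
            {"cell_id": grid.data["cell_id"].to_numpy(), "presence": presence}
        )
        if 0 < presence.sum() < len(presence):
            return OccurrenceSet(species=species, records=records)
        if niche.prevalence_target is None:
            # No target to steer toward: return the (one-class) draw as-is.
            return OccurrenceSet(species=species, records=records)
        # Re-centre: choose the intercept that sets mean probability to the
        # target, by bisection on the shifted logistic mean.
        intercept = _intercept_for_prevalence(linpred, niche.prevalence_target)
    raise DegenerateDataError(
        f"occurrences for {species!r} degenerate after {max_retries} retries"
    )


def _intercept_for_prevalence(linpred: np.ndarray, target: float) -> float:
    lo, hi = -60.0, 60.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(mid + linpred).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_growth_data(
    grid: ClimateGrid,
    population_cells: Sequence[str],
    n_fish_per_pop: int,
    max_age: int,
    resp: GrowthResponseSpec,
    seed: int,
    temp_variable: str = "annual_mean_temp",
) -> GrowthDataset:
    """Generate per-fish length-at-age observations with scale radii.

    Each population sits in one grid cell; its true (L∞, K) is the linear
    temperature response plus Gaussian noise. Each fish gets an integer last
    annulus age drawn uniformly on [1, max_age] and is captured a uniform
    fraction of a year later (fish are sampled during the growth season, so
    capture length exceeds length at the last annulus); its capture length
    is the von Bertalanffy length at the capture age times a mean-one
    lognormal factor with coefficient of variation ``length_cv``. That
    factor is individual size variability, so it scales the fish's whole
    trajectory — the length at the last annulus inherits it. Scale
    radii follow the linear scale–length relation (at capture length for
    S_c, at the noise-free length at the last annulus for S_a) plus a
    Gaussian reading error shared by the two radii — both are measured on
    the same scale image, so their errors are common-mode, which also keeps
    S_a ≤ S_c by construction. The scale-proportional back-calculation is
    exact in the noise-free limit. The emitted table carries the fractional
    capture age in ``age_capture`` alongside the annulus age ``age_t``.
    """
    if max_age < 2:
        raise InvalidArgumentError("max_age must be >= 2")
    if n_fish_per_pop < 1:
        raise InvalidArgumentError("n_fish_per_pop must be >= 1")
    cells = grid.cell_rows(population_cells)
    if temp_variable not in cells.columns:
        raise SchemaError(f"grid lacks temperature variable {temp_variable!r}")
    rng = derive_rng(seed, "growth_data")
    temps = cells[temp_variable].to_numpy(dtype=float)

    n_pop = len(cells)
    linf_true = (
        resp.Linf_intercept
        + resp.Linf_temp_slope * temps
        + rng.normal(0.0, resp.sd_Linf, n_pop)
    )
    k_true = (
        resp.K_intercept + resp.K_temp_slope * temps + rng.normal(0.0, resp.sd_K, n_pop)
    )
    if (linf_true <= 0).any() or (k_true <= 0).any():
        raise InvalidArgumentError(
            "growth response implies non-positive L-infinity or K in some population"
        )

    sigma = math.sqrt(math.log1p(resp.length_cv**2))
    rows = []
    truth = []
    for i in range(n_pop):
        pop_id = f"pop{i:03d}"
        cell_id = cells["cell_id"].iloc[i]
        truth.append(
            {
                "population_id": pop_id,
                "cell_id": cell_id,
                "temperature": temps[i],
                "Linf_true": linf_true[i],
                "K_true": k_true[i],
            }
        )
        ages = rng.integers(1, max_age + 1, n_fish_per_pop)
        frac = rng.uniform(0.0, 1.0, n_fish_per_pop)
        if sigma > 0:
            factor = np.exp(rng.normal(-0.5 * sigma**2, sigma, n_fish_per_pop))
        else:
            factor = np.ones(n_fish_per_pop)
        la = vbgf_length(linf_true[i], k_true[i], ages) * factor
        lc = vbgf_length(linf_true[i], k_true[i], ages + frac) * factor
        reading_err = rng.normal(0.0, resp.scale_sd, n_fish_per_pop)
        sc = resp.scale_intercept + resp.scale_slope * lc + reading_err
        sa = resp.scale_intercept + resp.scale_slope * la + reading_err
        sa = np.minimum(sa, sc)  # guards the boundary case la == lc
        if (sc <= 0).any() or (sa <= 0).any():
            raise InvalidArgumentError(
                "scale parameters produced non-positive scale radii"
            )
        for j in range(n_fish_per_pop):
            rows.append(
                {
                    "fish_id": f"{pop_id}_f{j:04d}",
                    "population_id": pop_id,
                    "cell_id": cell_id,
                    "age_t": int(ages[j]),
                    "age_capture": float(ages[j] + frac[j]),
                    "capture_length_mm": lc[j],
                    "scale_radius_capture": sc[j],
                    "scale_radius_annulus": sa[j],
                }
            )
    return GrowthDataset(pd.DataFrame(rows), pd.DataFrame(truth))
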