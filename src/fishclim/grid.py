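"""Gridded climate data container and scenario perturbation.

A :class:`ClimateGrid` holds one climate scenario on a regular lon/lat grid:
one row per cell, one column per bioclimatic variable. Six "core" variables
mirror the standard reduced bioclim set used for temperate freshwater fish
distribution modelling (annual mean temperature, mean diurnal range,
isothermality, mean temperature of the wettest and driest quarters, annual
precipitation); auxiliary variables (warmest-month maximum, coldest-month
minimum, annual range) carry the information needed to recompute derived
variables under warming scenarios and to exercise correlation-based variable
reduction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, SchemaError

#: Index / coordinate columns of the cell table.
COORD_COLUMNS = ("cell_id", "lon", "lat")

#: The six core variables retained for modelling.
CORE_VARIABLES = (
    "annual_mean_temp",
    "diurnal_range",
    "isothermality",
    "temp_wettest_quarter",
    "temp_driest_quarter",
    "annual_precip",
)

#: Auxiliary variables emitted by the synthetic generator.
AUX_VARIABLES = (
    "max_temp_warmest_month",
    "min_temp_coldest_month",
    "annual_temp_range",
)

#: Variables shifted additively by a warming scenario. Mean diurnal range is
#: deliberately not shifted: uniform warming cancels in a within-day range.
TEMPERATURE_VARIABLES = (
    "annual_mean_temp",
    "temp_wettest_quarter",
    "temp_driest_quarter",
    "max_temp_warmest_month",
    "min_temp_coldest_month",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One climate-change projection.

    Parameters
    ----------
    name:
        Unique label, e.g. ``"bcc_rcp26_2050"``.
    delta_temp:
        Additive shift (°C) applied to all temperature-type variables.
    precip_factor:
        Multiplicative factor on annual precipitation (must be > 0).
    year_label:
        Projection horizon label, e.g. ``"2050"``.
    """

    name: str
    delta_temp: float
    precip_factor: float = 1.0
    year_label: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.delta_temp):
            raise InvalidArgumentError("delta_temp must be finite")
        if not (self.precip_factor > 0 and math.isfinite(self.precip_factor)):
            raise InvalidArgumentError("precip_factor must be positive and finite")


@dataclass
class ClimateGrid:
    """Per-cell coordinates plus climate variables for one scenario.

    ``data`` must contain the columns ``cell_id``, ``lon``, ``lat`` and at
    least one variable column; cell ids must be unique and all variable
    values finite.
    """

    data: pd.DataFrame
    scenario_name: str = "baseline"

    def __post_init__(self) -> None:
        missing = [c for c in COORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"grid is missing columns {missing}")
        if self.data["cell_id"].duplicated().any():
            raise InvalidArgumentError("cell ids must be unique")
        if not self.variables:
            raise SchemaError("grid holds no climate variables")
        values = self.data[list(self.variables)].to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise InvalidArgumentError("climate values must all be finite")
        self.data = self.data.reset_index(drop=True)

    @property
    def variables(self) -> list[str]:
        """Names of the climate-variable columns (insertion order)."""
        return [c for c in self.data.columns if c not in COORD_COLUMNS]

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def values(self, variables: list[str] | None = None) -> np.ndarray:
        """Cell × variable matrix for the requested variables."""
        variables = list(variables) if variables is not None else self.variables
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise SchemaError(f"unknown climate variables {missing}")
        return self.data[variables].to_numpy(dtype=float)

    def cell_rows(self, cell_ids) -> pd.DataFrame:
        """Rows for the given cell ids, in the given order."""
        idx = self.data.set_index("cell_id")
        missing = [c for c in cell_ids if c not in idx.index]
        if missing:
            raise InvalidArgumentError(f"cells not in grid: {missing[:5]}")
        return idx.loc[list(cell_ids)].reset_index()

    def copy(self) -> "ClimateGrid":
        return dataclasses.replace(self, data=self.data.copy())


def recompute_isothermality(data: pd.DataFrame) -> None:
    """Recompute isothermality = 100 × diurnal range / annual range, in place.

    Requires the auxiliary warmest/coldest month columns; the annual range is
    itself refreshed from them first.
    """
    needed = ("diurnal_range", "max_temp_warmest_month", "min_temp_coldest_month")
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise SchemaError(f"cannot recompute isothermality without {missing}")
    annual_range = data["max_temp_warmest_month"] - data["min_temp_coldest_month"]
    if "annual_temp_range" in data.columns:
        data["annual_temp_range"] = annual_range
    data["isothermality"] = 100.0 * data["diurnal_range"] / annual_range


def apply_scenario(grid: ClimateGrid, scenario: ScenarioSpec) -> ClimateGrid:
    """Perturb a baseline grid into a projection scenario.

    Temperature-type variables are shifted by ``delta_temp``; annual
    precipitation is multiplied by ``precip_factor``; isothermality (and the
    annual temperature range) are recomputed from their definitions. Cell ids
    and coordinates are untouched.
    """
    out = grid.data.copy()
    for var in TEMPERATURE_VARIABLES:
        if var in out.columns:
            out[var] = out[var] + scenario.delta_temp
    if "annual_precip" in out.columns:
        out["annual_precip"] = out["annual_precip"] * scenario.precip_factor
    if "isothermality" in out.columns:
        recompute_isothermality(out)
    return ClimateGrid(out, scenario_name=scenario.name)


def write_climate_csv(grid: ClimateGrid, path) -> None:
    """Write a grid in long format: cell_id, lon, lat, variable, value."""
    long = grid.data.melt(
        id_vars=list(COORD_COLUMNS), var_name="variable", value_name="value"
    )
    long.insert(0, "scenario", grid.scenario_name)
    long.to_csv(path, index=False)


def read_climate_csv(path) -> ClimateGrid:
    """Read a grid written by :func:`write_climate_csv`."""
    long = pd.read_csv(path)
    needed = {"cell_id", "lon", "lat", "variable", "value"}
    missing = needed - set(long.columns)
    if missing:
        raise SchemaError(f"climate CSV missing columns {sorted(missing)}")
    scenario = "baseline"
    if "scenario" in long.columns and len(long):
        scenario = str(long["scenario"].iloc[0])
    wide = (
        long.pivot_table(
            index=["cell_id", "lon", "lat"], columns="variable", values="value",
            sort=False,
        )
        .reset_index()
        .rename_axis(columns=None)
    )
    return ClimateGrid(wide, scenario_name=scenario)
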