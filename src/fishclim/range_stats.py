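"""Range ("climate space") change statistics.

Occupied-cell counts and percent change, range centroids (mean coordinate of
presence cells), great-circle centroid displacement with initial bearing
(0° = north, clockwise), and two-sample t-tests on the latitude and
longitude distributions of presence cells before vs after projection. The
t statistics are signed as (original − projected), so a northward shift
gives a negative latitude t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidArgumentError, UndefinedStatisticError
from .sdm import PresenceGrid

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class Centroid:
    lon: float
    lat: float


@dataclass(frozen=True)
class Displacement:
    distance_km: float
    bearing_deg: float  # 0 = north, clockwise, in [0, 360)


@dataclass(frozen=True)
class ShiftTest:
    t_lat: float
    t_lon: float
    df_lat: float
    df_lon: float
    p_lat: float
    p_lon: float


def count_cells(pg: PresenceGrid) -> int:
    """Number of grid cells classified as climatically suitable."""
    return len(pg.presence_cells)


def percent_change(n_orig: int, n_pred: int) -> float:
    """Percent change in occupied cells, to two decimals."""
    if n_orig <= 0:
        raise UndefinedStatisticError("percent change undefined for n_orig <= 0")
    return round(100.0 * (n_pred - n_orig) / n_orig, 2)


def centroid(cells) -> Centroid:
    """Arithmetic mean coordinate of a set of (lon, lat) cells.

    This is the point about which the vector displacements of all presence
    cells sum to zero.
    """
    arr = np.asarray(list(cells), dtype=float)
    if arr.size == 0:
        raise InvalidArgumentError("centroid of an empty cell set is undefined")
    return Centroid(lon=float(arr[:, 0].mean()), lat=float(arr[:, 1].mean()))


def presence_coordinates(pg: PresenceGrid, grid) -> np.ndarray:
    """(lon, lat) array of the presence cells of ``pg`` on ``grid``."""
    idx = grid.data.set_index("cell_id")
    cells = sorted(pg.presence_cells)
    return idx.loc[cells, ["lon", "lat"]].to_numpy(dtype=float)


def displacement(c0: Centroid, c1: Centroid) -> Displacement:
    """Great-circle distance (haversine, R = 6371 km) and initial bearing."""
    lam0, phi0, lam1, phi1 = map(
        np.radians, (c0.lon, c0.lat, c1.lon, c1.lat)
    )
    dphi = phi1 - phi0
    dlam = lam1 - lam0
    a = np.sin(dphi / 2) ** 2 + np.cos(phi0) * np.cos(phi1) * np.sin(dlam / 2) ** 2
    dist = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    y = np.sin(dlam) * np.cos(phi1)
    x = np.cos(phi0) * np.sin(phi1) - np.sin(phi0) * np.cos(phi1) * np.cos(dlam)
    bearing = np.degrees(np.arctan2(y, x)) % 360.0
    if dist == 0.0:
        bearing = 0.0
    return Displacement(distance_km=float(dist), bearing_deg=float(bearing))


def coordinate_shift_test(
    cells_orig, cells_pred, equal_var: bool = False
) -> ShiftTest:
    """Two-sample t-tests on presence-cell latitudes and longitudes.

    Welch (unequal variance) by default; set ``equal_var=True`` for the
    pooled Student's t. Statistics are (original − projected) / SE.
    """
    a = np.asarray(list(cells_orig), dtype=float)
    b = np.asarray(list(cells_pred), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidArgumentError("each cell set needs >= 2 cells for a t-test")
    out = {}
    for name, col in (("lon", 0), ("lat", 1)):
        x, y = a[:, col], b[:, col]
        if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
            if x.mean() == y.mean():
                out[name] = (0.0, float(len(x) + len(y) - 2), 1.0)
                continue
            raise UndefinedStatisticError(
                f"zero variance in both {name} samples with unequal means"
            )
        res = stats.ttest_ind(x, y, equal_var=equal_var)
        out[name] = (float(res.statistic), float(res.df), float(res.pvalue))
    return ShiftTest(
        t_lat=out["lat"][0],
        t_lon=out["lon"][0],
        df_lat=out["lat"][1],
        df_lon=out["lon"][1],
        p_lat=out["lat"][2],
        p_lon=out["lon"][2],
    )


def scenario_range_summary(
    baseline_pg: PresenceGrid,
    scenario_pg: PresenceGrid,
    baseline_grid,
    scenario_grid,
    equal_var: bool = False,
) -> dict:
    """One row of the per-scenario range-change table."""
    coords0 = presence_coordinates(baseline_pg, baseline_grid)
    coords1 = presence_coordinates(scenario_pg, scenario_grid)
    n0, n1 = count_cells(baseline_pg), count_cells(scenario_pg)
    c0 = centroid(coords0)
    c1 = centroid(coords1)
    disp = displacement(c0, c1)
    test = coordinate_shift_test(coords0, coords1, equal_var=equal_var)
    return {
        "species": scenario_pg.species,
        "scenario": scenario_pg.scenario_name,
        "n_cells_orig": n0,
        "n_cells": n1,
        "pct_change": percent_change(n0, n1),
        "centroid_lon": c1.lon,
        "centroid_lat": c1.lat,
        "distance_km": disp.distance_km,
        "bearing_deg": disp.bearing_deg,
        "t_lat": test.t_lat,
        "t_lon": test.t_lon,
        "p_lat": test.p_lat,
        "p_lon": test.p_lon,
    }
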