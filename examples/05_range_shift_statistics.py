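"""Quantify a range shift: counts, centroid displacement, coordinate tests.

Uses two hand-built presence grids (a baseline and a poleward-expanded
projection) so every number is easy to follow.
"""

import numpy as np
import pandas as pd

import fishclim as fc
from fishclim.range_stats import (
    centroid, coordinate_shift_test, count_cells, displacement,
    percent_change, presence_coordinates,
)

grid = fc.generate_climate_grid(15, 20, seed=1)
lat = grid.data["lat"]
south = pd.Series((lat < 53.0).astype(float).values, index=grid.data["cell_id"])
shifted = pd.Series((lat < 54.5).astype(float).values, index=grid.data["cell_id"])

pg0 = fc.PresenceGrid("demo", "baseline", south, threshold=0.5)
pg1 = fc.PresenceGrid("demo", "warming", shifted, threshold=0.5)

n0, n1 = count_cells(pg0), count_cells(pg1)
print(f"occupied cells: {n0} -> {n1} ({percent_change(n0, n1):+.2f}%)")

c0 = centroid(presence_coordinates(pg0, grid))
c1 = centroid(presence_coordinates(pg1, grid))
disp = displacement(c0, c1)
print(f"centroid: ({c0.lon:.3f}, {c0.lat:.3f}) -> ({c1.lon:.3f}, {c1.lat:.3f})")
print(f"displacement: {disp.distance_km:.1f} km at bearing {disp.bearing_deg:.1f} deg "
      f"(0 = north, clockwise)")

test = coordinate_shift_test(
    presence_coordinates(pg0, grid), presence_coordinates(pg1, grid)
)
print(f"latitude t = {test.t_lat:.2f} (p = {test.p_lat:.2g}); "
      f"longitude t = {test.t_lon:.2f} (p = {test.p_lon:.2g})")
print("negative latitude t means the projected range lies further north.")
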