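"""Climate-variable reduction and spatial clipping.

Variable reduction follows the pairwise-correlation rule common in climate
envelope modelling: scan candidates in a caller-supplied priority order and
retain a variable only if its absolute Pearson correlation with every
already-retained variable stays at or below the threshold (default 0.70).
The priority order encodes which member of a correlated pair survives; the
default order is the six-variable reduced bioclim set.
"""

from __future__ import annotations

import logging

import numpy as np

from .exceptions import DegenerateDataError, InvalidArgumentError, SchemaError
from .grid import CORE_VARIABLES, ClimateGrid

log = logging.getLogger(__name__)

DEFAULT_CORRELATION_THRESHOLD = 0.70


def reduce_variables(
    grid: ClimateGrid,
    candidate_order: list[str] | None = None,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> list[str]:
    """Greedy correlation-based variable selection.

    Returns the retained variables in candidate order. Zero-variance
    candidates are excluded with a logged warning (their correlation is
    undefined). Deterministic for a given grid and order.
    """
    if candidate_order is None:
        candidate_order = [v for v in CORE_VARIABLES if v in grid.variables]
    if len(candidate_order) < 2:
        raise InvalidArgumentError("need at least two candidate variables")
    missing = [v for v in candidate_order if v not in grid.variables]
    if missing:
        raise SchemaError(f"candidates not present in grid: {missing}")

    X = grid.values(candidate_order)
    stds = X.std(axis=0)
    retained: list[str] = []
    retained_cols: list[int] = []
    for j, name in enumerate(candidate_order):
        if stds[j] == 0.0:
            log.warning("excluding zero-variance variable %r", name)
            continue
        ok = True
        for k in retained_cols:
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            if abs(r) > threshold:
                ok = False
                break
        if ok:
            retained.append(name)
            retained_cols.append(j)
    return retained


def clip_to_region(grid: ClimateGrid, cell_mask) -> ClimateGrid:
    """Restrict a grid to the cells named in ``cell_mask``.

    Variables are untouched; an empty intersection raises.
    """
    mask = set(cell_mask)
    if not mask:
        raise InvalidArgumentError("cell mask must be non-empty")
    keep = grid.data["cell_id"].isin(mask)
    if not keep.any():
        raise DegenerateDataError("cell mask does not intersect the grid")
    return ClimateGrid(
        grid.data.loc[keep].reset_index(drop=True), scenario_name=grid.scenario_name
    )
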