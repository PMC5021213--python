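"""Scale back-calculation and von Bertalanffy growth fitting.

Workflow per species: regress scale radius at capture on capture length
(ordinary least squares), back-calculate each fish's length at its last
annulus with the scale-proportional formula, then fit the two-parameter von
Bertalanffy growth function

    L(t) = L∞ · (1 − exp(−K · t))

to the (age, back-calculated length) points of each population by nonlinear
least squares. The two-parameter form pins L(0) = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DegenerateDataError, InvalidArgumentError

log = logging.getLogger(__name__)

#: Required columns of a growth-observation table.
OBSERVATION_COLUMNS = (
    "fish_id",
    "population_id",
    "cell_id",
    "age_t",
    "capture_length_mm",
    "scale_radius_capture",
    "scale_radius_annulus",
)


@dataclass(frozen=True)
class ScaleBodyRegression:
    """OLS fit of scale radius on body length: S = u + v·L."""

    intercept_u: float
    slope_v: float
    r2: float

    def __post_init__(self) -> None:
        if self.slope_v <= 0:
            raise InvalidArgumentError(
                "scale-body slope must be positive for back-calculation"
            )


@dataclass(frozen=True)
class GrowthParams:
    """Fitted von Bertalanffy parameters for one population."""

    population_id: str
    Linf: float
    K: float
    n_fish: int
    rss: float
    converged: bool


def vbgf_length(Linf, K, t):
    """Two-parameter von Bertalanffy length at age: L∞(1 − e^(−Kt))."""
    return Linf * (1.0 - np.exp(-K * np.asarray(t, dtype=float)))


def fit_scale_body_regression(obs: pd.DataFrame) -> ScaleBodyRegression:
    """OLS of scale radius at capture on capture length.

    Needs at least three observations with distinct lengths; a non-positive
    slope makes back-calculation undefined and raises.
    """
    lengths = obs["capture_length_mm"].to_numpy(dtype=float)
    radii = obs["scale_radius_capture"].to_numpy(dtype=float)
    if len(lengths) < 3:
        raise DegenerateDataError("need >= 3 observations for scale-body regression")
    if np.unique(lengths).size < 2:
        raise DegenerateDataError("capture lengths are all identical; OLS undefined")
    res = stats.linregress(lengths, radii)
    return ScaleBodyRegression(
        intercept_u=float(res.intercept),
        slope_v=float(res.slope),
        r2=float(res.rvalue**2),
    )


def backcalculate_length(
    capture_length: float,
    scale_radius_capture: float,
    scale_radius_annulus: float,
    reg: ScaleBodyRegression,
) -> float:
    """Scale-proportional back-calculated length at the last annulus.

    L_a = −(u/v) + (L_c + u/v) · (S_a / S_c). Equals L_c when S_a = S_c.
    """
    ratio = reg.intercept_u / reg.slope_v
    return -ratio + (capture_length + ratio) * (
        scale_radius_annulus / scale_radius_capture
    )


def backcalculate_table(obs: pd.DataFrame, reg: ScaleBodyRegression) -> pd.DataFrame:
    """Back-calculate the whole observation table.

    Returns a copy with a ``length_at_annulus_mm`` column; observations whose
    back-calculated length is non-positive are dropped with a logged warning.
    """
    out = obs.copy()
    ratio = reg.intercept_u / reg.slope_v
    out["length_at_annulus_mm"] = -ratio + (
        out["capture_length_mm"] + ratio
    ) * (out["scale_radius_annulus"] / out["scale_radius_capture"])
    bad = out["length_at_annulus_mm"] <= 0
    if bad.any():
        log.warning(
            "dropping %d observations with non-positive back-calculated length",
            int(bad.sum()),
        )
        out = out.loc[~bad]
    return out.reset_index(drop=True)


def fit_vbgf(
    ages, lengths, population_id: str = "", max_iter: int = 500
) -> GrowthParams:
    """Fit L(t) = L∞(1 − e^(−Kt)) by nonlinear least squares.

    Starts from L∞₀ = 1.1 × max length and a K₀ obtained by regressing
    −log(1 − L/L∞₀) on age through the origin. Returns ``converged=False``
    (with the best parameters found) on non-convergence or unidentifiable
    data such as a single repeated length.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if t.size < 3:
        raise DegenerateDataError("need >= 3 length-at-age points")
    if np.unique(t).size < 2:
        raise DegenerateDataError("need >= 2 distinct ages")
    if np.ptp(y) == 0.0:
        # A flat length profile carries no growth signal.
        return GrowthParams(population_id, float(y[0]), np.nan, t.size, 0.0, False)

    linf0 = 1.1 * float(y.max())
    frac = np.clip(y / linf0, 1e-9, 1.0 - 1e-9)
    z = -np.log1p(-frac)
    k0 = float(np.dot(t, z) / np.dot(t, t))
    k0 = max(k0, 1e-6)

    def residuals(p):
        return vbgf_length(p[0], p[1], t) - y

    res = optimize.least_squares(
        residuals,
        x0=[linf0, k0],
        bounds=([1e-9, 1e-9], [np.inf, np.inf]),
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=max_iter,
    )
    linf, k = (float(v) for v in res.x)
    rss = float(np.sum(res.fun**2))
    return GrowthParams(population_id, linf, k, int(t.size), rss, bool(res.success))


def fit_populations(
    obs: pd.DataFrame,
    reg: ScaleBodyRegression | None = None,
    per_population_regression: bool = False,
    min_fish: int = 3,
) -> pd.DataFrame:
    """Back-calculate and fit the growth model for every population.

    By default a single species-level scale–length regression is used; with
    ``per_population_regression`` each population gets its own. Populations
    with fewer than ``min_fish`` usable fish are skipped with a warning.

    Returns a table with columns population_id, cell_id, Linf_mm, K_per_yr,
    n_fish, rss, converged.
    """
    if reg is None and not per_population_regression:
        reg = fit_scale_body_regression(obs)
    rows = []
    for pop_id, group in obs.groupby("population_id", sort=True):
        pop_reg = fit_scale_body_regression(group) if per_population_regression else reg
        back = backcalculate_table(group, pop_reg)
        if len(back) < min_fish or back["age_t"].nunique() < 2:
            warnings.warn(
                f"population {pop_id}: too few usable fish for a growth fit; skipped",
                stacklevel=2,
            )
            continue
        params = fit_vbgf(
            back["age_t"], back["length_at_annulus_mm"], population_id=str(pop_id)
        )
        rows.append(
            {
                "population_id": params.population_id,
                "cell_id": group["cell_id"].iloc[0],
                "Linf_mm": params.Linf,
                "K_per_yr": params.K,
                "n_fish": params.n_fish,
                "rss": params.rss,
                "converged": params.converged,
            }
        )
    return pd.DataFrame(rows)
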