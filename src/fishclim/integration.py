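"""Coupling of range-shift and growth-shift predictions.

The scenario-mean growth parameters (L∞, K) are regressed on the percent
change in climate space across scenarios (simple linear regression with an
F-test of zero slope; with eight projections the F degrees of freedom are
(1, 6)). Predicted per-population (L∞, K) pairs are also turned into
per-scenario von Bertalanffy length-at-age curves with empirical 95%
percentile bands across populations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateDataError, InvalidArgumentError
from .growth import vbgf_length
from .growth_climate import GrowthProjection


@dataclass(frozen=True)
class CouplingRegression:
    """OLS of a scenario-mean growth parameter on percent climate-space change."""

    target: str
    slope: float
    intercept: float
    r2: float
    F: float
    df1: int
    df2: int
    p: float
    n_scenarios: int


@dataclass
class GrowthCurveSet:
    """Mean length-at-age curve with 95% percentile band, one scenario."""

    scenario_name: str
    curve: pd.DataFrame  # columns: age, mean_mm, lo_mm, hi_mm


def fit_coupling_regression(
    pct_changes, mean_params, target: str = ""
) -> CouplingRegression:
    """Simple linear regression with F-test of zero slope.

    ``pct_changes`` (percent) is the predictor, the scenario means of a
    growth parameter the response. For simple regression F = t² of the slope
    and r² = F/(F + df₂).
    """
    x = np.asarray(pct_changes, dtype=float)
    y = np.asarray(mean_params, dtype=float)
    if len(x) < 3:
        raise DegenerateDataError("need >= 3 scenarios for the coupling regression")
    if np.ptp(x) == 0.0:
        raise InvalidArgumentError("all percent-change values identical; slope undefined")
    res = stats.linregress(x, y)
    df2 = len(x) - 2
    t = res.slope / res.stderr if res.stderr > 0 else np.inf
    return CouplingRegression(
        target=target,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        F=float(t**2),
        df1=1,
        df2=df2,
        p=float(res.pvalue),
        n_scenarios=len(x),
    )


def build_growth_curves(proj: GrowthProjection, max_age: int) -> GrowthCurveSet:
    """Length-at-age curves across populations for one scenario.

    Evaluates the von Bertalanffy function at integer ages 0..max_age for
    every population's predicted (L∞, K); the mean curve is the per-age mean
    and the band the 2.5th/97.5th percentiles across populations.
    """
    valid = proj.per_population.loc[proj.per_population["valid"]]
    if len(valid) < 2:
        raise DegenerateDataError("need >= 2 valid populations for growth curves")
    ages = np.arange(0, max_age + 1)
    linf = valid["Linf_hat_mm"].to_numpy()[:, None]
    k = valid["K_hat_per_yr"].to_numpy()[:, None]
    lengths = vbgf_length(linf, k, ages[None, :])
    curve = pd.DataFrame(
        {
            "age": ages,
            "mean_mm": lengths.mean(axis=0),
            "lo_mm": np.percentile(lengths, 2.5, axis=0),
            "hi_mm": np.percentile(lengths, 97.5, axis=0),
        }
    )
    return GrowthCurveSet(scenario_name=proj.scenario_name, curve=curve)


def scenario_report(
    species_results: list[dict], seed: int, config: dict | None = None
) -> dict:
    """Collate per-species results into one machine-readable report.

    Each entry of ``species_results`` is a dict with keys ``species``,
    ``range_table`` (DataFrame), ``growth_means`` (DataFrame),
    ``coupling`` (list of CouplingRegression) and ``curves`` (list of
    GrowthCurveSet). Deterministic for a given seed and config.
    """
    report = {
        "seed": int(seed),
        "config": config or {},
        "species": [],
    }
    for res in species_results:
        entry = {
            "species": res["species"],
            "range_table": res["range_table"].to_dict(orient="records"),
            "growth_means": res["growth_means"].to_dict(orient="records"),
            "coupling": [asdict(c) for c in res.get("coupling", [])],
            "curves": [
                {
                    "scenario": cs.scenario_name,
                    "curve": cs.curve.to_dict(orient="records"),
                }
                for cs in res.get("curves", [])
            ],
        }
        report["species"].append(entry)
    # Round-trip through JSON so the structure is guaranteed serializable.
    return json.loads(json.dumps(report, default=float))
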