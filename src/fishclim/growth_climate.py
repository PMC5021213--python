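"""Climate models of growth parameters and their GCV-weighted ensemble.

Per-population asymptotic length (L∞, mm) and growth coefficient (K, yr⁻¹)
are modelled separately as functions of the retained climate variables with
three regression families:

* GLM — Gaussian generalized linear model fit by iteratively reweighted
  least squares;
* GAM — penalized B-spline additive model (4 degrees of freedom per smooth;
  cubic and quadratic bases tried, the minimum-GCV one kept; penalty weight
  chosen by generalized cross-validation);
* MARS — adaptive piecewise-linear regression (forward step accepted only
  above a 0.001 R² gain, backward pruning by cross-validation).

Each family's skill score is its leave-one-out mean squared prediction
error, referred to throughout as GCV; ensemble weights are proportional to
1/GCV. Goodness of fit of the ensemble is the RMSE between observed and
predicted values under baseline climate. Spline-based predictors clamp new
covariates to the training range, so projections beyond the observed climate
flatten rather than extrapolate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

from ._mars import MarsRegressor
from .exceptions import DegenerateDataError, InvalidArgumentError
from .grid import ClimateGrid

log = logging.getLogger(__name__)

GROWTH_FAMILIES = ("GLM", "GAM", "MARS")

#: Degrees of freedom per GAM smooth term (the 4-knot cap).
GAM_DF = 4
#: Candidate B-spline degrees for the GAM (cubic and quadratic bases).
GAM_DEGREES = (3, 2)
MARS_RSQ_STEP = 0.001
MARS_CV_FOLDS = 30


@dataclass
class GrowthClimateModel:
    """One fitted family for one growth parameter.

    ``predict`` maps a climate matrix (columns in ``climate_vars`` order) to
    target units; ``refit`` refits the same configuration on new data and
    returns a predictor — this is what exact leave-one-out needs.
    """

    target: str
    family: str
    climate_vars: list[str]
    predict: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    refit: Callable[[np.ndarray, np.ndarray], Callable] = field(repr=False)
    gcv: float = float("nan")
    meta: dict = field(default_factory=dict)

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        return self.predict(table[self.climate_vars].to_numpy(dtype=float))


@dataclass
class GrowthEnsemble:
    """Inverse-GCV-weighted mean of the fitted families."""

    target: str
    members: list[tuple[str, float]]
    models: dict = field(repr=False, default_factory=dict)
    rmse_baseline: float = float("nan")

    @property
    def weights(self) -> dict[str, float]:
        return dict(self.members)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for family, w in self.members:
            out += w * self.models[family].predict(X)
        return out

    def predict_table(self, table: pd.DataFrame) -> np.ndarray:
        vars_ = self.models[self.members[0][0]].climate_vars
        return self.predict(table[vars_].to_numpy(dtype=float))


@dataclass
class GrowthProjection:
    """Per-population growth-parameter predictions under one scenario."""

    scenario_name: str
    per_population: pd.DataFrame
    mean_Linf: float
    se_Linf: float
    ci_Linf: tuple[float, float]
    mean_K: float
    se_K: float
    ci_K: tuple[float, float]
    n_valid: int
    n_excluded: int = 0


def _extract_xy(table: pd.DataFrame, target: str, climate_vars: Sequence[str]):
    X = table[list(climate_vars)].to_numpy(dtype=float)
    y = table[target].to_numpy(dtype=float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise InvalidArgumentError("growth-climate table contains missing values")
    return X, y


def _fit_glm(X, y):
    if np.ptp(y) == 0.0:
        # constant response: IRLS is degenerate, the fit is the constant
        const = float(y[0])
        params = np.zeros(X.shape[1] + 1)
        params[0] = const
        return (lambda Xn: np.full(len(np.asarray(Xn)), const)), {"params": params}
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-fit chatter on nested truths
        res = sm.GLM(y, design, family=sm.families.Gaussian()).fit()  # IRLS

    def predict(Xn):
        return np.asarray(
            res.predict(sm.add_constant(np.asarray(Xn, float), has_constant="add"))
        )

    return predict, {"params": np.asarray(res.params)}


def _fit_gam_one(X, y, degree):
    bs = BSplines(X, df=[GAM_DF] * X.shape[1], degree=[degree] * X.shape[1])
    gam = GLMGam(y, smoother=bs, family=sm.families.Gaussian())
    gam.fit()
    try:
        # GCV-driven penalty search; seeded so runs are reproducible
        alpha = gam.select_penweight(criterion="gcv", seed=0)[0]
    except Exception:  # singular/ill-conditioned penalty search
        alpha = np.zeros(X.shape[1])
    res = GLMGam(y, smoother=bs, alpha=alpha, family=sm.families.Gaussian()).fit()
    lo, hi = X.min(axis=0), X.max(axis=0)

    def predict(Xn):
        Xc = np.clip(np.asarray(Xn, float), lo, hi)
        return np.asarray(res.predict(exog_smooth=Xc))

    return predict, alpha


def _fit_mars(X, y, seed=0):
    reg = MarsRegressor(
        rsq_threshold=MARS_RSQ_STEP, n_cv_folds=MARS_CV_FOLDS, seed=seed
    )
    reg.fit(X, y)
    return reg.predict, {"n_terms": len(reg.terms_)}


def fit_growth_family(
    table: pd.DataFrame,
    target: str,
    family: str,
    climate_vars: Sequence[str],
    min_populations: int = 10,
) -> GrowthClimateModel:
    """Fit one regression family for one growth parameter.

    ``table`` holds one row per population with the target column and the
    climate variables at the population's cell. The returned model carries
    its leave-one-out GCV score. For the GAM, both candidate spline bases
    are fitted and the minimum-GCV one kept.
    """
    if family not in GROWTH_FAMILIES:
        raise InvalidArgumentError(f"unknown growth model family {family!r}")
    X, y = _extract_xy(table, target, climate_vars)
    if len(y) < min_populations:
        raise DegenerateDataError(
            f"need >= {min_populations} populations, got {len(y)}"
        )

    if family == "GLM":
        predict, meta = _fit_glm(X, y)

        def refit(Xs, ys):
            return _fit_glm(Xs, ys)[0]

        model = GrowthClimateModel(
            target=target, family=family, climate_vars=list(climate_vars),
            predict=predict, refit=refit, meta=meta,
        )
        model.gcv = compute_gcv(model, table)
        return model

    if family == "MARS":
        predict, meta = _fit_mars(X, y)

        def refit(Xs, ys):
            return _fit_mars(Xs, ys)[0]

        model = GrowthClimateModel(
            target=target, family=family, climate_vars=list(climate_vars),
            predict=predict, refit=refit, meta=meta,
        )
        model.gcv = compute_gcv(model, table)
        return model

    # GAM: try both spline bases, keep the minimum-GCV one.
    best = None
    for degree in GAM_DEGREES:
        try:
            predict, alpha = _fit_gam_one(X, y, degree)
        except Exception as exc:
            log.warning("GAM basis degree=%d failed for %s: %s", degree, target, exc)
            continue

        def refit(Xs, ys, _degree=degree, _alpha=alpha):
            bs = BSplines(
                Xs, df=[GAM_DF] * Xs.shape[1], degree=[_degree] * Xs.shape[1]
            )
            res = GLMGam(
                ys, smoother=bs, alpha=_alpha, family=sm.families.Gaussian()
            ).fit()
            lo, hi = Xs.min(axis=0), Xs.max(axis=0)
            return lambda Xn: np.asarray(
                res.predict(exog_smooth=np.clip(np.asarray(Xn, float), lo, hi))
            )

        model = GrowthClimateModel(
            target=target, family=family, climate_vars=list(climate_vars),
            predict=predict, refit=refit,
            meta={"degree": degree, "alpha": np.asarray(alpha)},
        )
        model.gcv = compute_gcv(model, table)
        if best is None or model.gcv < best.gcv:
            best = model
    if best is None:
        raise DegenerateDataError(f"no GAM basis could be fitted for {target}")
    return best


def loo_mse_refit(model: GrowthClimateModel, X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out mean squared prediction error by explicit refits."""
    n = len(y)
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            predictor = model.refit(X[mask], y[mask])
        preds[i] = float(np.atleast_1d(predictor(X[i : i + 1]))[0])
    return float(np.mean((y - preds) ** 2))


def loo_mse_hat(X: np.ndarray, y: np.ndarray) -> float:
    """Closed-form LOO MSE for OLS with intercept (linear-smoother identity)."""
    design = sm.add_constant(np.asarray(X, float), has_constant="add")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    h = np.einsum("ij,ji->i", design, np.linalg.pinv(design))
    return float(np.mean((resid / (1.0 - h)) ** 2))


def compute_gcv(model: GrowthClimateModel, table: pd.DataFrame) -> float:
    """GCV of a fitted model: leave-one-out mean squared prediction error.

    For the GLM (a linear smoother) the closed-form hat-matrix identity is
    used; other families are scored by exact refits.
    """
    X, y = _extract_xy(table, model.target, model.climate_vars)
    if len(y) < 3:
        raise DegenerateDataError("GCV undefined for fewer than 3 rows")
    if model.family == "GLM":
        return loo_mse_hat(X, y)
    return loo_mse_refit(model, X, y)


def build_growth_ensemble(members: Sequence[GrowthClimateModel]) -> GrowthEnsemble:
    """Weight the fitted families by inverse GCV (lower GCV ⇒ better fit).

    A member with GCV exactly zero predicts perfectly under leave-one-out;
    such members take all the weight, split equally among ties.
    """
    members = [m for m in members if np.isfinite(m.gcv)]
    if not members:
        raise InvalidArgumentError("no valid member models")
    targets = {m.target for m in members}
    if len(targets) != 1:
        raise InvalidArgumentError(f"members target different parameters: {targets}")
    zero = [m for m in members if m.gcv == 0.0]
    if zero:
        pairs = [(m.family, 1.0 / len(zero)) for m in zero]
        models = {m.family: m for m in zero}
    else:
        inv = np.array([1.0 / m.gcv for m in members])
        w = inv / inv.sum()
        pairs = [(m.family, float(wi)) for m, wi in zip(members, w)]
        models = {m.family: m for m in members}
    return GrowthEnsemble(target=members[0].target, members=pairs, models=models)


def fit_growth_ensemble(
    table: pd.DataFrame,
    target: str,
    climate_vars: Sequence[str],
    families: Sequence[str] = GROWTH_FAMILIES,
) -> GrowthEnsemble:
    """Fit all families (skipping any that fail, with a warning) and combine."""
    fitted = []
    for family in families:
        try:
            fitted.append(fit_growth_family(table, target, family, climate_vars))
        except DegenerateDataError:
            raise
        except Exception as exc:
            warnings.warn(
                f"{family} failed for {target} and is excluded: {exc}", stacklevel=2
            )
    ens = build_growth_ensemble(fitted)
    ens.rmse_baseline = assess_rmse(ens, table)
    return ens


def assess_rmse(ens: GrowthEnsemble, table: pd.DataFrame) -> float:
    """Root mean squared error of the ensemble under baseline climate."""
    y = table[ens.target].to_numpy(dtype=float)
    pred = ens.predict_table(table)
    return float(np.sqrt(np.mean((y - pred) ** 2)))


def project_growth(
    ens_Linf: GrowthEnsemble,
    ens_K: GrowthEnsemble,
    scenario_grid: ClimateGrid,
    populations: pd.DataFrame,
) -> GrowthProjection:
    """Predict per-population (L∞, K) under a scenario's climate.

    ``populations`` needs columns ``population_id`` and ``cell_id``. Scenario
    means carry the standard error over populations and a t-based 95%
    confidence interval; populations with a non-positive predicted parameter
    are excluded from the means with a logged count.
    """
    cells = scenario_grid.cell_rows(populations["cell_id"].tolist())
    linf_hat = ens_Linf.predict_table(cells)
    k_hat = ens_K.predict_table(cells)
    per_pop = pd.DataFrame(
        {
            "population_id": populations["population_id"].to_numpy(),
            "cell_id": populations["cell_id"].to_numpy(),
            "Linf_hat_mm": linf_hat,
            "K_hat_per_yr": k_hat,
        }
    )
    valid = (linf_hat > 0) & (k_hat > 0)
    per_pop["valid"] = valid
    n_excl = int((~valid).sum())
    if n_excl:
        log.warning(
            "%s: excluded %d populations with non-positive predictions",
            scenario_grid.scenario_name,
            n_excl,
        )
    sub = per_pop.loc[valid]
    n = len(sub)
    if n == 0:
        raise DegenerateDataError("no population has valid predicted parameters")

    def summarize(vals):
        mean = float(vals.mean())
        if n < 2:
            warnings.warn("single population: SE/CI undefined", stacklevel=3)
            return mean, float("nan"), (float("nan"), float("nan"))
        se = float(vals.std(ddof=1) / np.sqrt(n))
        tcrit = float(stats.t.ppf(0.975, n - 1))
        return mean, se, (mean - tcrit * se, mean + tcrit * se)

    mean_l, se_l, ci_l = summarize(sub["Linf_hat_mm"])
    mean_k, se_k, ci_k = summarize(sub["K_hat_per_yr"])
    return GrowthProjection(
        scenario_name=scenario_grid.scenario_name,
        per_population=per_pop,
        mean_Linf=mean_l,
        se_Linf=se_l,
        ci_Linf=ci_l,
        mean_K=mean_k,
        se_K=se_k,
        ci_K=ci_k,
        n_valid=n,
        n_excluded=n_excl,
    )
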