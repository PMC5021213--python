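"""Multi-algorithm species distribution modelling and AUC-weighted ensembles.

Seven classifier families model presence/absence from climate: GLM (logistic
regression), GAM (spline-basis logistic regression capped at 4 knots), MARS
(piecewise-linear adaptive regression on the 0/1 response), CTA
(classification tree), BRT (gradient-boosted trees), RF (random forest) and
ANN (multilayer perceptron). Each is evaluated by repeated stratified 80:20
splits scored with the rank-based AUC; models whose mean AUC passes the
cutoff are refit on all data and combined by an AUC-weighted mean of their
presence probabilities; thresholding the ensemble probability yields the
predicted presence grid ("climate space").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

from ._mars import MarsRegressor
from ._rng import derive_seed
from .exceptions import (
    DegenerateDataError,
    InvalidArgumentError,
    NoSkilledModelError,
    SchemaError,
    UndefinedStatisticError,
)
from .grid import ClimateGrid

log = logging.getLogger(__name__)

ALGORITHM_IDS = ("GLM", "GAM", "MARS", "CTA", "BRT", "RF", "ANN")

DEFAULT_AUC_CUTOFF = 0.7
DEFAULT_PRESENCE_THRESHOLD = 0.6
DEFAULT_N_REPS = 50
DEFAULT_TRAIN_FRAC = 0.8

#: Knot cap for the GAM smoother, to avoid overfitting.
GAM_KNOTS = 4


@dataclass
class OccurrenceSet:
    """Presence/absence records for one species on grid cells.

    Modelling requires both classes; construction merely warns on a
    one-class set (a saturated niche can legitimately produce one), and the
    split/AUC machinery raises when such a set reaches it.
    """

    species: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"cell_id", "presence"} - set(self.records.columns)
        if missing:
            raise SchemaError(f"occurrence records missing columns {sorted(missing)}")
        values = set(self.records["presence"].unique().tolist())
        if not values <= {0, 1}:
            raise InvalidArgumentError("presence must be coded 0/1")
        if values != {0, 1}:
            log.warning(
                "occurrence set for %s holds a single class; unusable for SDM",
                self.species,
            )

    @property
    def prevalence(self) -> float:
        return float(self.records["presence"].mean())


@dataclass
class AlgorithmReport:
    """Repeated-split evaluation summary for one algorithm."""

    algo_id: str
    mean_auc: float
    auc_per_rep: np.ndarray
    included: bool


@dataclass
class EnsembleModel:
    """AUC-weighted mean of the skilled single models, refit on all data."""

    species: str
    variables: list[str]
    members: list[tuple[str, float]]
    models: dict = field(repr=False, default_factory=dict)
    auc_cutoff: float = DEFAULT_AUC_CUTOFF
    ensemble_auc_resub: float = float("nan")
    ensemble_auc_holdout: float = float("nan")
    reports: dict = field(repr=False, default_factory=dict)

    @property
    def weights(self) -> dict[str, float]:
        return dict(self.members)

    def predict_prob(self, grid: ClimateGrid) -> pd.Series:
        """Ensemble presence probability per cell of ``grid``."""
        X = grid.values(self.variables)
        p = np.zeros(len(X))
        for algo_id, w in self.members:
            p += w * _predict_prob(self.models[algo_id], X)
        return pd.Series(p, index=grid.data["cell_id"].to_numpy(), name="probability")


@dataclass
class PresenceGrid:
    """Thresholded ensemble prediction for one species × scenario."""

    species: str
    scenario_name: str
    cell_probabilities: pd.Series
    threshold: float

    @property
    def presence_cells(self) -> set:
        return set(
            self.cell_probabilities.index[
                self.cell_probabilities >= self.threshold
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_probabilities.index,
                "probability": self.cell_probabilities.to_numpy(),
                "presence": (
                    self.cell_probabilities >= self.threshold
                ).astype(int).to_numpy(),
            }
        )


def compute_auc(scores, labels) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties ½.

    Equivalent to the Mann–Whitney U statistic normalised by n₁·n₀.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError("AUC undefined with a single class")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def make_estimator(algo_id: str, seed: int = 0):
    """Instantiate one classifier family with its standard settings."""
    if algo_id == "GLM":
        return LogisticRegression(C=1e4, max_iter=2000)
    if algo_id == "GAM":
        return make_pipeline(
            SplineTransformer(n_knots=GAM_KNOTS, degree=3, extrapolation="constant"),
            LogisticRegression(max_iter=2000),
        )
    if algo_id == "MARS":
        return _MarsClassifier()
    if algo_id == "CTA":
        return DecisionTreeClassifier(random_state=seed)
    if algo_id == "BRT":
        return GradientBoostingClassifier(random_state=seed)
    if algo_id == "RF":
        return RandomForestClassifier(random_state=seed)
    if algo_id == "ANN":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(8,), max_iter=500, random_state=seed
            ),
        )
    raise InvalidArgumentError(f"unknown algorithm id {algo_id!r}")


class _MarsClassifier:
    """MARS on a 0/1 response; probabilities are the clipped fit."""

    def __init__(self) -> None:
        self._reg = MarsRegressor()

    def fit(self, X, y):
        self._reg.fit(np.asarray(X, float), np.asarray(y, float))
        return self

    def predict_prob(self, X):
        return np.clip(self._reg.predict(np.asarray(X, float)), 0.0, 1.0)


def _predict_prob(model, X) -> np.ndarray:
    if hasattr(model, "predict_prob"):
        return model.predict_prob(X)
    return model.predict_proba(X)[:, 1]


def _fit_quiet(est, X, y):
    """Fit suppressing optimizer convergence chatter (ANN on hard splits)."""
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def design_matrix(
    occ: OccurrenceSet, grid: ClimateGrid, variables: list[str] | None = None
):
    """Join occurrences to grid climate: (X, y, variables)."""
    variables = list(variables) if variables is not None else grid.variables
    merged = occ.records.merge(
        grid.data[["cell_id", *variables]], on="cell_id", how="left", validate="1:1"
    )
    if merged[variables].isna().any().any():
        bad = merged.loc[merged[variables].isna().any(axis=1), "cell_id"]
        raise SchemaError(f"occurrence cells missing from grid: {list(bad[:5])}")
    return (
        merged[variables].to_numpy(dtype=float),
        merged["presence"].to_numpy(dtype=int),
        variables,
    )


def _stratified_splits(y, n_reps, train_frac, seed, max_retries=5):
    from sklearn.model_selection import StratifiedShuffleSplit

    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise DegenerateDataError(
            "need at least two records per class for stratified splitting"
        )
    for attempt in range(max_retries):
        splitter = StratifiedShuffleSplit(
            n_splits=n_reps,
            train_size=train_frac,
            random_state=derive_seed(seed, "splits", attempt),
        )
        splits = list(splitter.split(np.zeros_like(y), y))
        if all(
            len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2
            for tr, te in splits
        ):
            return splits
    raise DegenerateDataError("could not draw two-class train/test splits")


def evaluate_algorithms(
    occ: OccurrenceSet,
    grid: ClimateGrid,
    algo_ids=ALGORITHM_IDS,
    variables: list[str] | None = None,
    n_reps: int = DEFAULT_N_REPS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
    seed: int = 0,
):
    """Evaluate every algorithm over a shared set of stratified splits.

    Returns ``(reports, holdout)`` where ``reports`` maps algorithm id to
    :class:`AlgorithmReport` and ``holdout`` keeps the per-repetition test
    indices and member test scores so an ensemble AUC can later be computed
    on genuinely held-out data.
    """
    X, y, variables = design_matrix(occ, grid, variables)
    splits = _stratified_splits(y, n_reps, train_frac, seed)
    reports: dict[str, AlgorithmReport] = {}
    test_scores: dict[str, list[np.ndarray]] = {}
    for algo_id in algo_ids:
        aucs = np.empty(len(splits))
        scores_per_rep = []
        for rep, (train, test) in enumerate(splits):
            est = make_estimator(algo_id, seed=derive_seed(seed, algo_id, rep))
            _fit_quiet(est, X[train], y[train])
            scores = _predict_prob(est, X[test])
            scores_per_rep.append(scores)
            aucs[rep] = compute_auc(scores, y[test])
        mean_auc = float(aucs.mean())
        reports[algo_id] = AlgorithmReport(
            algo_id=algo_id,
            mean_auc=mean_auc,
            auc_per_rep=aucs,
            included=mean_auc >= auc_cutoff,
        )
        test_scores[algo_id] = scores_per_rep
    holdout = {"splits": splits, "test_scores": test_scores, "labels": y}
    return reports, holdout


def evaluate_algorithm(
    occ: OccurrenceSet,
    grid: ClimateGrid,
    algo_id: str,
    variables: list[str] | None = None,
    n_reps: int = DEFAULT_N_REPS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
    seed: int = 0,
) -> AlgorithmReport:
    """Repeated-split AUC evaluation of a single algorithm."""
    reports, _ = evaluate_algorithms(
        occ,
        grid,
        algo_ids=(algo_id,),
        variables=variables,
        n_reps=n_reps,
        train_frac=train_frac,
        auc_cutoff=auc_cutoff,
        seed=seed,
    )
    return reports[algo_id]


def build_ensemble(
    reports: dict[str, AlgorithmReport],
    models: dict[str, object],
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
) -> list[tuple[str, float]]:
    """Membership and weights of the AUC-weighted ensemble.

    Members are the algorithms with mean AUC ≥ cutoff; weights are their mean
    AUCs normalised to sum to one.
    """
    passing = [r for r in reports.values() if r.mean_auc >= auc_cutoff]
    if not passing:
        raise NoSkilledModelError(
            f"no algorithm reached mean AUC >= {auc_cutoff}"
        )
    total = sum(r.mean_auc for r in passing)
    members = [(r.algo_id, r.mean_auc / total) for r in passing]
    missing = [a for a, _ in members if a not in models]
    if missing:
        raise InvalidArgumentError(f"no fitted model supplied for {missing}")
    return members


def fit_sdm_ensemble(
    occ: OccurrenceSet,
    grid: ClimateGrid,
    algo_ids=ALGORITHM_IDS,
    variables: list[str] | None = None,
    n_reps: int = DEFAULT_N_REPS,
    train_frac: float = DEFAULT_TRAIN_FRAC,
    auc_cutoff: float = DEFAULT_AUC_CUTOFF,
    seed: int = 0,
) -> EnsembleModel:
    """Evaluate, select, refit on full data and assemble the ensemble.

    Evaluation AUCs are used only for member selection and weighting; the
    final member models are refit on all records. Two ensemble AUCs are
    reported: resubstitution (ensemble scored on its own training data) and
    held-out (ensemble of within-split member fits scored on each
    repetition's test fold, then averaged).
    """
    X, y, variables = design_matrix(occ, grid, variables)
    reports, holdout = evaluate_algorithms(
        occ,
        grid,
        algo_ids=algo_ids,
        variables=variables,
        n_reps=n_reps,
        train_frac=train_frac,
        auc_cutoff=auc_cutoff,
        seed=seed,
    )
    models = {
        algo_id: _fit_quiet(
            make_estimator(algo_id, seed=derive_seed(seed, algo_id, "full")), X, y
        )
        for algo_id in algo_ids
    }
    members = build_ensemble(reports, models, auc_cutoff=auc_cutoff)
    member_ids = [a for a, _ in members]
    log.info(
        "ensemble for %s: members %s", occ.species,
        {a: round(w, 3) for a, w in members},
    )

    p_resub = np.zeros(len(X))
    for algo_id, w in members:
        p_resub += w * _predict_prob(models[algo_id], X)
    auc_resub = compute_auc(p_resub, y)

    holdout_aucs = []
    for rep, (_, test) in enumerate(holdout["splits"]):
        p = np.zeros(len(test))
        for algo_id, w in members:
            p += w * holdout["test_scores"][algo_id][rep]
        holdout_aucs.append(compute_auc(p, y[test]))
    return EnsembleModel(
        species=occ.species,
        variables=variables,
        members=members,
        models={a: models[a] for a in member_ids},
        auc_cutoff=auc_cutoff,
        ensemble_auc_resub=float(auc_resub),
        ensemble_auc_holdout=float(np.mean(holdout_aucs)),
        reports=reports,
    )


def predict_presence(
    ens: EnsembleModel,
    grid: ClimateGrid,
    threshold: float = DEFAULT_PRESENCE_THRESHOLD,
) -> PresenceGrid:
    """Threshold the ensemble probability into a presence grid."""
    if not (0.0 <= threshold <= 1.0):
        raise InvalidArgumentError("threshold must lie in [0, 1]")
    probs = ens.predict_prob(grid)
    return PresenceGrid(
        species=ens.species,
        scenario_name=grid.scenario_name,
        cell_probabilities=probs,
        threshold=threshold,
    )
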