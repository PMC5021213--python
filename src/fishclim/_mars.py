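"""Multivariate adaptive regression splines (additive hinge basis).

A compact MARS: the forward pass greedily adds reflected hinge pairs
max(x−k, 0) / max(k−x, 0) while each step improves R² by at least
``rsq_threshold`` (default 0.001); the backward pass prunes basis functions
by cross-validated mean squared error (``n_cv_folds`` folds, capped at the
sample size — at that cap the score is the exact leave-one-out MSE via the
hat-matrix identity). Interactions between variables are not modelled; the
fit is piecewise-linear additive, which extrapolates linearly beyond the
training range.
"""

from __future__ import annotations

import numpy as np

from ._rng import derive_rng


def _hinge(x: np.ndarray, knot: float, sign: int) -> np.ndarray:
    return np.maximum(sign * (x - knot), 0.0)


def _ols_rss(B: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _loo_mse(B: np.ndarray, y: np.ndarray) -> float:
    """Closed-form leave-one-out MSE for an OLS fit on basis ``B``."""
    n, p = B.shape
    if n <= p:
        return float("inf")
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    # Hat diagonal via the pseudo-inverse, robust to rank deficiency.
    Bp = np.linalg.pinv(B)
    h = np.einsum("ij,ji->i", B, Bp)
    denom = 1.0 - h
    if np.any(denom <= 1e-10):
        return float("inf")
    return float(np.mean((resid / denom) ** 2))


def _kfold_mse(B: np.ndarray, y: np.ndarray, folds: list[np.ndarray]) -> float:
    n = len(y)
    pred = np.empty(n)
    for test in folds:
        train = np.setdiff1d(np.arange(n), test)
        if len(train) <= B.shape[1]:
            return float("inf")
        coef, *_ = np.linalg.lstsq(B[train], y[train], rcond=None)
        pred[test] = B[test] @ coef
    return float(np.mean((y - pred) ** 2))


class MarsRegressor:
    """Additive piecewise-linear MARS with CV backward pruning.

    Parameters
    ----------
    rsq_threshold:
        Minimum R² improvement required to accept a forward step.
    n_cv_folds:
        Folds for backward pruning (capped at n; the cap gives exact LOO).
    max_knots_per_var:
        Candidate knots per variable, taken at interior quantiles.
    max_terms:
        Hard cap on hinge basis functions (excluding the intercept).
    seed:
        Seed for the fold assignment when k < n.
    """

    def __init__(
        self,
        rsq_threshold: float = 0.001,
        n_cv_folds: int = 30,
        max_knots_per_var: int = 15,
        max_terms: int = 20,
        seed: int = 0,
    ) -> None:
        self.rsq_threshold = rsq_threshold
        self.n_cv_folds = n_cv_folds
        self.max_knots_per_var = max_knots_per_var
        self.max_terms = max_terms
        self.seed = seed
        self.terms_: list[tuple[int, float, int]] = []
        self.coef_: np.ndarray | None = None

    # -- basis -----------------------------------------------------------
    def _basis(self, X: np.ndarray, terms) -> np.ndarray:
        cols = [np.ones(len(X))]
        cols.extend(_hinge(X[:, v], k, s) for v, k, s in terms)
        return np.column_stack(cols)

    def _candidate_knots(self, x: np.ndarray) -> np.ndarray:
        uniq = np.unique(x)
        if len(uniq) <= 2:
            return np.empty(0)
        interior = uniq[1:-1]
        if len(interior) <= self.max_knots_per_var:
            return interior
        qs = np.linspace(0.0, 1.0, self.max_knots_per_var + 2)[1:-1]
        return np.unique(np.quantile(x, qs))

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        tss = float(np.sum((y - y.mean()) ** 2))
        terms: list[tuple[int, float, int]] = []
        if tss == 0.0:
            self.terms_ = terms
            self.coef_, _ = _ols_rss(self._basis(X, terms), y)
            return self

        candidates = [
            (v, float(k))
            for v in range(X.shape[1])
            for k in self._candidate_knots(X[:, v])
        ]
        _, rss = _ols_rss(self._basis(X, terms), y)
        while len(terms) < self.max_terms and candidates:
            best = None
            B_cur = self._basis(X, terms)
            for v, k in candidates:
                pair = [(v, k, 1), (v, k, -1)]
                B_try = np.column_stack(
                    [B_cur, _hinge(X[:, v], k, 1), _hinge(X[:, v], k, -1)]
                )
                _, rss_try = _ols_rss(B_try, y)
                if best is None or rss_try < best[0]:
                    best = (rss_try, v, k, pair)
            rss_try, v, k, pair = best
            if (rss - rss_try) / tss < self.rsq_threshold:
                break
            terms.extend(pair)
            rss = rss_try
            candidates.remove((v, k))

        terms = self._prune(X, y, terms)
        self.terms_ = terms
        self.coef_, _ = _ols_rss(self._basis(X, terms), y)
        return self

    def _cv_score(self, X, y, terms, folds) -> float:
        B = self._basis(X, terms)
        if folds is None:
            return _loo_mse(B, y)
        return _kfold_mse(B, y, folds)

    def _prune(self, X, y, terms):
        n = len(y)
        k = min(self.n_cv_folds, n)
        if k >= n:
            folds = None  # exact LOO, closed form
        else:
            idx = derive_rng(self.seed, "mars_folds").permutation(n)
            folds = [f for f in np.array_split(idx, k)]
        best_score = self._cv_score(X, y, terms, folds)
        improved = True
        while improved and terms:
            improved = False
            scores = [
                self._cv_score(X, y, terms[:i] + terms[i + 1 :], folds)
                for i in range(len(terms))
            ]
            i_best = int(np.argmin(scores))
            if scores[i_best] <= best_score:
                terms = terms[:i_best] + terms[i_best + 1 :]
                best_score = scores[i_best]
                improved = True
        return terms

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._basis(X, self.terms_) @ self.coef_
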