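import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import fishclim as fc
from fishclim.exceptions import (
    DegenerateDataError,
    InvalidArgumentError,
    NoSkilledModelError,
    UndefinedStatisticError,
)
from fishclim.sdm import (
    AlgorithmReport,
    EnsembleModel,
    build_ensemble,
    compute_auc,
    evaluate_algorithm,
    predict_presence,
)


def brute_force_auc(scores, labels):
    """All positive–negative pair counting, ties ½ (independent oracle)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestComputeAUC:
    def test_perfect_separation(self):
        assert compute_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert compute_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert compute_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_one_class_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compute_auc([0.1, 0.2], [1, 1])

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 60))
            scores = rng.choice(np.round(rng.random(8), 2), size=n)  # many ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert compute_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    @given(st.floats(0.1, 5.0))
    def test_invariant_under_monotone_transform(self, scale):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.2])
        labels = np.array([0, 0, 1, 1, 0])
        assert compute_auc(scale * scores, labels) == compute_auc(scores, labels)


class TestEvaluateAlgorithm:
    def test_separable_niche_scores_high(self, small_grid):
        # perfectly separable: presence iff temperature above its median
        t = small_grid.data["annual_mean_temp"]
        occ = fc.OccurrenceSet(
            "separable",
            pd.DataFrame(
                {
                    "cell_id": small_grid.data["cell_id"],
                    "presence": (t > t.median()).astype(int),
                }
            ),
        )
        for algo in ("GLM", "RF"):
            rep = evaluate_algorithm(occ, small_grid, algo, n_reps=10, seed=1)
            assert rep.mean_auc >= 0.95
            assert rep.included

    def test_permuted_labels_score_near_half(self, small_grid):
        rng = np.random.default_rng(2)
        records = pd.DataFrame(
            {
                "cell_id": small_grid.data["cell_id"],
                "presence": rng.permutation(
                    np.repeat([0, 1], small_grid.n_cells // 2)
                ),
            }
        )
        occ = fc.OccurrenceSet("null_species", records)
        rep = evaluate_algorithm(occ, small_grid, "GLM", n_reps=20, seed=3)
        assert 0.4 <= rep.mean_auc <= 0.6

    def test_fixed_seed_reproduces_rep_aucs(self, small_grid, separable_occurrences):
        a = evaluate_algorithm(separable_occurrences, small_grid, "CTA", n_reps=6, seed=9)
        b = evaluate_algorithm(separable_occurrences, small_grid, "CTA", n_reps=6, seed=9)
        np.testing.assert_array_equal(a.auc_per_rep, b.auc_per_rep)

    def test_too_few_minority_records_error(self, small_grid):
        records = pd.DataFrame(
            {
                "cell_id": small_grid.data["cell_id"],
                "presence": [1] + [0] * (small_grid.n_cells - 1),
            }
        )
        occ = fc.OccurrenceSet("rare", records)
        with pytest.raises(DegenerateDataError):
            evaluate_algorithm(occ, small_grid, "GLM", n_reps=3, seed=0)


class _ConstProb:
    def __init__(self, p):
        self.p = np.asarray(p, float)

    def predict_prob(self, X):
        return self.p[: len(X)]


def report(algo, auc):
    return AlgorithmReport(algo, auc, np.array([auc]), auc >= 0.7)


class TestBuildEnsemble:
    def test_single_passing_member_takes_all_weight(self):
        members = build_ensemble({"RF": report("RF", 0.9)}, {"RF": object()})
        assert members == [("RF", 1.0)]

    def test_equal_aucs_split_evenly(self):
        members = build_ensemble(
            {"RF": report("RF", 0.8), "GLM": report("GLM", 0.8)},
            {"RF": object(), "GLM": object()},
        )
        assert dict(members) == {"RF": pytest.approx(0.5), "GLM": pytest.approx(0.5)}

    def test_weights_proportional_to_auc(self):
        members = dict(
            build_ensemble(
                {"A": report("A", 0.9), "B": report("B", 0.75)},
                {"A": object(), "B": object()},
            )
        )
        assert members["A"] == pytest.approx(0.9 / 1.65)
        assert members["B"] == pytest.approx(0.75 / 1.65)

    def test_cutoff_filters_members_and_can_empty(self):
        reports = {"A": report("A", 0.65), "B": report("B", 0.72)}
        members = build_ensemble(reports, {"B": object()}, auc_cutoff=0.7)
        assert [a for a, _ in members] == ["B"]
        with pytest.raises(NoSkilledModelError):
            build_ensemble({"A": report("A", 0.6)}, {}, auc_cutoff=0.7)


def hand_ensemble(grid, probs_by_member, weights):
    models = {k: _ConstProb(v) for k, v in probs_by_member.items()}
    return EnsembleModel(
        species="sp",
        variables=grid.variables[:1],
        members=list(weights.items()),
        models=models,
    )


class TestPredictPresence:
    def small5(self):
        data = pd.DataFrame(
            {
                "cell_id": list("abcde"),
                "lon": np.zeros(5),
                "lat": np.zeros(5),
                "x": np.arange(5.0),
            }
        )
        return fc.ClimateGrid(data)

    def test_hand_set_weighted_mean_and_threshold(self):
        grid = self.small5()
        ens = hand_ensemble(
            grid,
            {"A": [0.9, 0.8, 0.5, 0.2, 0.0], "B": [0.7, 0.2, 0.5, 0.8, 0.2]},
            {"A": 0.75, "B": 0.25},
        )
        pg = predict_presence(ens, grid, threshold=0.6)
        expected = 0.75 * np.array([0.9, 0.8, 0.5, 0.2, 0.0]) + 0.25 * np.array(
            [0.7, 0.2, 0.5, 0.8, 0.2]
        )
        np.testing.assert_allclose(pg.cell_probabilities.to_numpy(), expected)
        assert pg.presence_cells == {"a", "b"}

    def test_threshold_extremes(self):
        grid = self.small5()
        ens = hand_ensemble(grid, {"A": [0.1, 0.5, 0.3, 0.9, 0.2]}, {"A": 1.0})
        assert len(predict_presence(ens, grid, 0.0).presence_cells) == 5
        assert predict_presence(ens, grid, 1.0).presence_cells == set()

    def test_count_non_increasing_in_threshold(self):
        grid = self.small5()
        ens = hand_ensemble(grid, {"A": [0.1, 0.5, 0.3, 0.9, 0.2]}, {"A": 1.0})
        counts = [
            len(predict_presence(ens, grid, th).presence_cells)
            for th in np.linspace(0, 1, 11)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold(self):
        grid = self.small5()
        ens = hand_ensemble(grid, {"A": [0.1] * 5}, {"A": 1.0})
        with pytest.raises(InvalidArgumentError):
            predict_presence(ens, grid, 1.5)


class TestEnsembleProperties:
    def test_fitted_ensemble_contracts(self, small_grid, separable_occurrences):
        ens = fc.fit_sdm_ensemble(
            separable_occurrences,
            small_grid,
            algo_ids=("GLM", "CTA", "RF"),
            n_reps=8,
            seed=4,
        )
        weights = np.array([w for _, w in ens.members])
        assert abs(weights.sum() - 1.0) < 1e-12
        assert (weights >= 0).all()
        # ensemble probability bounded by member probabilities, cell-wise
        X = small_grid.values(ens.variables)
        member_probs = np.vstack(
            [ens.models[a].predict_proba(X)[:, 1] for a, _ in ens.members]
        )
        p = ens.predict_prob(small_grid).to_numpy()
        assert (p >= member_probs.min(axis=0) - 1e-12).all()
        assert (p <= member_probs.max(axis=0) + 1e-12).all()
        assert 0.5 < ens.ensemble_auc_holdout <= 1.0
        assert 0.5 < ens.ensemble_auc_resub <= 1.0
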