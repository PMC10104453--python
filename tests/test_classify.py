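"""L1 logistic fitting, LOPO cross-validation, lambda selection, metrics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from adhf_voice.classify import (
    ConvergenceWarning,
    CVResult,
    classification_metrics,
    fit_final_model,
    fit_l1_logistic,
    lambda_grid,
    logistic_loss,
    lopo_cv,
    odds_ratios,
    select_lambda,
)
from adhf_voice.cohort import build_model_input
from adhf_voice.synthgen import CohortSpec, synth_cohort


def toy_data(n=20, m=3, seed=0, beta=(1.0, -0.5, 0.0)):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, m))
    p = 1.0 / (1.0 + np.exp(-(X @ np.asarray(beta))))
    y = np.where(rng.random(n) < p, 1.0, -1.0)
    return X, y


def separated_cohort(n_participants=40, shift=1.5, seed=0):
    """Synthetic cohort with several features shifted ~1.5 SD between classes."""
    effects = {f"t:f{j}": shift * (-1) ** j for j in range(6)}
    spec = CohortSpec(
        n_participants=n_participants,
        effects=effects,
        missing_rate=0.0,
        single_day_fraction=0.0,
        seed=seed,
    )
    table, _ = synth_cohort(spec)
    return build_model_input(table)


class TestLogisticLoss:
    def test_closed_forms(self):
        assert logistic_loss(np.array(1.0), np.array(0.0)) == pytest.approx(math.log(2))
        assert logistic_loss(np.array(-1.0), np.array(1.0)) == pytest.approx(
            math.log(1 + math.e)
        )

    def test_limit_and_stability(self):
        assert logistic_loss(np.array(1.0), np.array(1e4)) == pytest.approx(0.0, abs=1e-12)
        # large opposite-sign margins stay finite and ~linear
        val = logistic_loss(np.array(1.0), np.array(-1e4))
        assert np.isfinite(val) and val == pytest.approx(1e4, rel=1e-6)


class TestFitL1Logistic:
    def test_matches_unpenalized_reference(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X, y = toy_data()
        model = fit_l1_logistic(X, y, 0.0)
        ref = sklearn.LogisticRegression(C=np.inf, tol=1e-12, max_iter=20_000).fit(X, y)
        assert np.max(np.abs(model.beta - ref.coef_[0])) < 1e-4
        assert abs(model.beta0 - ref.intercept_[0]) < 1e-4

    def test_objective_no_worse_than_zero_vector(self):
        X, y = toy_data(seed=3)
        for lam in (0.0, 0.05, 0.5):
            model = fit_l1_logistic(X, y, lam)
            obj = np.mean(logistic_loss(y, model.decision(X))) + lam * np.abs(model.beta).sum()
            obj0 = np.mean(logistic_loss(y, np.zeros(len(y))))
            assert obj <= obj0 + 1e-10

    def test_large_lambda_zeroes_weights_and_predicts_majority(self):
        X, y = toy_data(seed=1)
        model = fit_l1_logistic(X, y, 10.0)
        assert np.all(model.beta == 0.0)
        majority = 1.0 if (y == 1).sum() >= (y == -1).sum() else -1.0
        assert np.all(model.predict(X) == majority)

    def test_separable_two_points_classified(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array([-1.0, 1.0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model = fit_l1_logistic(X, y, 0.0, max_iter=2000)
        assert not model.converged
        np.testing.assert_array_equal(model.predict(X), y)

    def test_sparsity_monotone_in_lambda(self):
        X, y = toy_data(n=40, seed=2)
        nonzeros = [
            int((fit_l1_logistic(X, y, lam).beta != 0).sum()) for lam in lambda_grid()
        ]
        assert all(a >= b for a, b in zip(nonzeros, nonzeros[1:]))

    def test_planted_coefficient_sign_recovered(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((80, 4))
            y = np.where(rng.random(80) < 1 / (1 + np.exp(-1.2 * X[:, 0])), 1.0, -1.0)
            if len(np.unique(y)) < 2:
                continue
            model = fit_l1_logistic(X, y, 0.01)
            hits += model.beta[0] > 0
        assert hits / n_seeds >= 0.95

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_l1_logistic(np.ones((4, 2)), np.ones(4), 0.1)


class TestLambdaGrid:
    def test_default_grid(self):
        grid = lambda_grid()
        assert len(grid) == 30
        assert grid[0] == pytest.approx(0.001)
        assert grid[-1] == pytest.approx(1.0)

    def test_constant_geometric_ratio(self):
        grid = lambda_grid()
        ratios = grid[1:] / grid[:-1]
        assert ratios == pytest.approx(np.full(29, (1.0 / 0.001) ** (1 / 29)))

    def test_two_points(self):
        assert lambda_grid(2, 0.1, 10.0) == pytest.approx([0.1, 10.0])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            lambda_grid(5, 1.0, 0.1)


class TestLopoCV:
    def test_one_fold_per_participant_each_row_scored_once(self):
        mi = separated_cohort(12)
        cv = lopo_cv(mi.X, mi.y, mi.participants, 0.05)
        assert len(cv.records) == len(mi)
        assert cv.records.scored.all()
        counts = cv.records.groupby("participant").size()
        assert (counts == 2).all()

    def test_planted_separation_classified_above_080(self):
        mi = separated_cohort(40, shift=1.5, seed=0)
        cv = lopo_cv(mi.X, mi.y, mi.participants, 0.05)
        assert cv.metrics["accuracy"] > 0.80

    def test_confusion_counts_sum_to_scored_rows(self):
        mi = separated_cohort(10)
        cv = lopo_cv(mi.X, mi.y, mi.participants, 0.1)
        assert sum(cv.confusion.values()) == int(cv.records.scored.sum())

    def test_too_few_participants_rejected(self):
        X = np.zeros((4, 1))
        y = np.array([1.0, -1.0, 1.0, -1.0])
        with pytest.raises(ValueError):
            lopo_cv(X, y, np.array(["a", "a", "b", "b"]), 0.1)

    def test_label_permutation_accuracy_near_chance(self):
        """No-leakage check: permuted labels score near 0.5."""
        mi = separated_cohort(52, seed=1)
        in_band = 0
        n_seeds = 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            # permute admission/discharge within participants
            y_perm = mi.y.copy()
            for pid in np.unique(mi.participants):
                idx = np.flatnonzero(mi.participants == pid)
                y_perm[idx] = rng.permutation(y_perm[idx])
            if len(np.unique(y_perm)) < 2:
                continue
            cv = lopo_cv(mi.X, y_perm, mi.participants, 0.05)
            in_band += 0.35 <= cv.metrics["accuracy"] <= 0.65
        assert in_band / n_seeds >= 0.90


class TestSelectLambda:
    def test_noise_labels_prefer_heavy_shrinkage(self):
        rng = np.random.default_rng(0)
        n = 60
        X = rng.standard_normal((n, 6))
        y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        parts = np.repeat([f"p{i}" for i in range(n // 2)], 2)
        lam, _ = select_lambda(X, y, parts)
        assert lam >= np.median(lambda_grid())

    def test_strong_signal_prefers_light_shrinkage(self):
        mi = separated_cohort(30, shift=2.0, seed=2)
        lam, table = select_lambda(mi.X, mi.y, mi.participants)
        assert lam < lambda_grid()[-1]
        assert len(table) == 30

    def test_grid_of_one(self):
        mi = separated_cohort(8)
        lam, _ = select_lambda(mi.X, mi.y, mi.participants, grid=np.array([0.07]))
        assert lam == 0.07


class TestMetrics:
    @staticmethod
    def _cv_from_counts(ta, fa, fd, td):
        rows = []
        rows += [("p", 1, 1, 0.2, True)] * ta
        rows += [("p", 1, -1, 0.8, True)] * fd
        rows += [("p", -1, -1, 0.9, True)] * td
        rows += [("p", -1, 1, 0.3, True)] * fa
        records = pd.DataFrame(
            rows, columns=["participant", "y_true", "y_pred", "p_discharge", "scored"]
        )
        return CVResult(records=records, lam=0.1)

    def test_hand_computed_confusion_arithmetic(self):
        cv = self._cv_from_counts(ta=8, fa=2, fd=3, td=7)
        m = classification_metrics(cv)
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["tar"] == pytest.approx(8 / 11)
        assert m["tdr"] == pytest.approx(7 / 9)
        assert m["apv"] == pytest.approx(0.8)
        assert m["dpv"] == pytest.approx(0.7)

    def test_perfectly_separated_probabilities_auc_one(self):
        records = pd.DataFrame(
            {
                "participant": list("abcd"),
                "y_true": [1, 1, -1, -1],
                "y_pred": [1, 1, -1, -1],
                "p_discharge": [0.1, 0.2, 0.8, 0.9],
                "scored": True,
            }
        )
        assert classification_metrics(CVResult(records, 0.1))["auc"] == 1.0

    def test_all_tied_probabilities_auc_half(self):
        records = pd.DataFrame(
            {
                "participant": list("abcd"),
                "y_true": [1, 1, -1, -1],
                "y_pred": [1, 1, 1, 1],
                "p_discharge": [0.4] * 4,
                "scored": True,
            }
        )
        assert classification_metrics(CVResult(records, 0.1))["auc"] == 0.5

    def test_absent_class_gives_missing_metrics(self):
        records = pd.DataFrame(
            {
                "participant": ["a", "b"],
                "y_true": [1, 1],
                "y_pred": [1, -1],
                "p_discharge": [0.2, 0.6],
                "scored": True,
            }
        )
        m = classification_metrics(CVResult(records, 0.1))
        assert math.isnan(m["auc"]) and math.isnan(m["tdr"])
        assert m["tar"] == pytest.approx(0.5)


class TestOddsRatios:
    def test_closed_forms_and_ordering(self):
        mi = separated_cohort(20)
        model = fit_final_model(mi, 0.05)
        table = odds_ratios(model)
        assert len(table) == len(mi.feature_names)
        np.testing.assert_allclose(table.odds_ratio, np.exp(table.beta))
        np.testing.assert_allclose(
            table.discharge_odds_ratio, np.exp(-table.beta)
        )
        mags = np.abs(table.beta.to_numpy())
        assert np.all(np.diff(mags) <= 1e-12)

    def test_zero_and_log2_coefficients(self):
        from adhf_voice.classify import LogisticModel

        model = LogisticModel(
            beta0=0.0, beta=np.array([0.0, math.log(2)]), lam=0.1,
            feature_names=("a", "b"),
        )
        table = odds_ratios(model).set_index("feature")
        assert table.loc["a", "odds_ratio"] == pytest.approx(1.0)
        assert table.loc["b", "odds_ratio"] == pytest.approx(2.0)
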