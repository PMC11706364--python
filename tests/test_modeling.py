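import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipopanel import (
    biomarker_characterization,
    cutoff_curves,
    evaluate_models,
    impute_and_log,
    rf_importance,
    roc_auc,
    youden_cutoff,
)

from conftest import make_toy_table


def pairwise_auc(scores, labels):
    """Brute-force concordance: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def scan_youden(scores, labels):
    """Exhaustive scan over every threshold between consecutive unique scores."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2
    candidates = np.concatenate([[u[0]], mids, [u[-1] + max((u[-1] - u[0]) / 2, 1.0)]])
    best = -np.inf
    for c in candidates:
        pred = scores >= c
        sens = np.mean(pred[labels == 1]) if (labels == 1).any() else 0
        spec = np.mean(~pred[labels == 0]) if (labels == 0).any() else 0
        best = max(best, sens + spec - 1)
    return best


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == pytest.approx(1.0)

    def test_all_ties_give_half(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]).auc == pytest.approx(0.5)

    def test_hand_case_three_quarters(self):
        assert roc_auc([0.8, 0.4, 0.6, 0.2], [1, 1, 0, 0]).auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_pairwise_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 25)
        labels = np.zeros(n)
        labels[: rng.integers(1, n - 1)] = 1
        scores = np.round(rng.normal(size=n), rng.integers(0, 3))  # ties likely
        curve = roc_auc(scores, labels)
        assert curve.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
        assert np.all(np.diff(curve.fpr) >= 0) and np.all(np.diff(curve.tpr) >= 0)

    def test_score_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, 20)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels).auc
        b = roc_auc(-scores, labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestYouden:
    def test_perfect_case_midpoint_cutoff(self):
        curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        cutoff, j = youden_cutoff(curve)
        assert j == pytest.approx(1.0)
        assert cutoff == pytest.approx(0.5)  # midpoint of the separating gap

    def test_constant_scores_give_zero_j(self):
        curve = roc_auc([0.3] * 8, [1, 1, 1, 1, 0, 0, 0, 0])
        _, j = youden_cutoff(curve)
        assert j == pytest.approx(0.0)

    def test_six_point_toy_matches_scan(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1])
        curve = roc_auc(scores, labels)
        cutoff, j = youden_cutoff(curve)
        assert j == pytest.approx(scan_youden(scores, labels))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 20)
        labels = np.zeros(n)
        labels[: rng.integers(1, n - 1)] = 1
        scores = np.round(rng.normal(size=n), 2)
        curve = roc_auc(scores, labels)
        cutoff, j = youden_cutoff(curve)
        assert j == pytest.approx(scan_youden(scores, labels), abs=1e-12)
        # reported J must be achieved at the reported cutoff
        pred = scores >= cutoff
        sens = np.mean(pred[labels == 1])
        spec = np.mean(~pred[labels == 0])
        assert sens + spec - 1 == pytest.approx(j, abs=1e-12)


class TestCutoffCurves:
    def test_grid_extremes(self):
        scores = np.array([0.2, 0.6, 0.4, 0.9])
        labels = np.array([0, 1, 0, 1])
        tab = cutoff_curves(scores, labels)
        first = tab.iloc[0]
        assert first["cutoff"] == 0.0 and first["sensitivity"] == 1.0 and first["specificity"] == 0.0
        last = tab.iloc[-1]
        assert last["sensitivity"] == 0.0 or last["cutoff"] <= scores.max()
        assert ((tab[["accuracy", "sensitivity", "specificity"]] >= 0).all().all())
        assert ((tab[["accuracy", "sensitivity", "specificity"]] <= 1).all().all())

    def test_best_accuracy_beats_the_extremes(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 50)
        scores = np.clip(0.3 + 0.4 * labels + rng.normal(0, 0.1, 100), 0, 1)
        tab = cutoff_curves(scores, labels)
        assert tab["accuracy"].max() >= tab["accuracy"].iloc[0]
        assert tab["accuracy"].max() >= tab["accuracy"].iloc[-1]


def _biomarker_problem(seed=0, n=80, delta=2.0):
    rng = np.random.default_rng(seed)
    y = np.repeat([0.0, 1.0], n // 2)
    X = pd.DataFrame(
        {
            "1033NEG": 15 + delta * y + rng.normal(0, 0.8, n),
            "877NEG": 12 + delta * y + rng.normal(0, 0.8, n),
        }
    )
    return X, y


class TestEvaluateModels:
    def test_planted_signal_all_models_discriminate(self):
        X, y = _biomarker_problem(seed=1)
        report = evaluate_models(X, y, folds=5, repeats=2, seed=0)
        med = report.metrics.groupby("model")["auc"].median()
        assert set(med.index) == {"LR", "RF", "SVM"}
        assert (med >= 0.9).all()
        assert len(report.metrics) == 5 * 2 * 3
        assert report.metrics[["auc", "sensitivity", "specificity"]].min().min() >= 0
        assert report.metrics[["auc", "sensitivity", "specificity"]].max().max() <= 1

    def test_null_biomarkers_center_at_chance(self):
        # study-scale n: at small n an unregularized fit on pure noise
        # anti-learns and its CV AUC dips well below 0.5
        X, y = _biomarker_problem(seed=2, n=200, delta=0.0)
        report = evaluate_models(X, y, folds=5, repeats=4, seed=0)
        mean_auc = report.metrics.groupby("model")["auc"].mean()
        assert ((mean_auc - 0.5).abs() < 0.1).all()

    def test_same_seed_identical_report(self):
        X, y = _biomarker_problem(seed=3)
        r1 = evaluate_models(X, y, folds=4, repeats=2, seed=5)
        r2 = evaluate_models(X, y, folds=4, repeats=2, seed=5)
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)


class TestRfImportance:
    def test_normalized_and_signal_dominates_noise(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat([0.0, 1.0], 40)
            X = pd.DataFrame(
                {"signal": 2.0 * y + rng.normal(0, 1, 80), "noise": rng.normal(0, 1, 80)}
            )
            imp = rf_importance(X, y, n_trees=200, seed=seed)
            assert imp.sum() == pytest.approx(1.0)
            wins += imp["signal"] > imp["noise"]
        assert wins >= 9

    def test_constant_feature_near_zero(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0.0, 1.0], 30)
        X = pd.DataFrame({"flat": np.full(60, 3.0), "useful": y + rng.normal(0, 0.3, 60)})
        imp = rf_importance(X, y, seed=0, n_trees=100)
        assert imp["flat"] < 0.05


class TestCharacterization:
    def test_summary_and_self_correlation(self, small_dataset):
        table, truth = small_dataset
        log = impute_and_log(table)
        summary, r, p = biomarker_characterization(log, truth["strong"])
        for fid in truth["strong"]:
            assert summary.loc[fid, "welch_p"] < 0.01  # planted group difference
            assert r.loc[fid, fid] == pytest.approx(1.0)
        pair = truth["strong"]
        assert abs(r.loc[pair[0], pair[1]]) < 0.5  # independent plants: low overlap

    def test_absent_biomarker_named_in_error(self, toy_table):
        with pytest.raises(KeyError, match="999POS"):
            biomarker_characterization(toy_table, ["999POS"])
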