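"""Confusion-matrix metrics, AUC, thresholds, filters and importance."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdmcascade import (
    ConfusionMatrix,
    auc,
    confusion,
    filter_runs,
    optimal_threshold,
    permutation_importance,
    scores_from_confusion,
)


def naive_scores(tp, fp, fn, tn):
    """Independent reimplementation straight from the metric definitions."""
    n = tp + fp + fn + tn
    out = {}
    out["sens"] = tp / (tp + fn) if tp + fn else math.nan
    out["spec"] = tn / (tn + fp) if tn + fp else math.nan
    out["ppp"] = tp / (tp + fp) if tp + fp else math.nan
    out["npp"] = tn / (tn + fn) if tn + fn else math.nan
    out["pcc"] = (tp + tn) / n
    pe = ((tp + fn) / n) * ((tp + fp) / n) + ((tn + fp) / n) * ((tn + fn) / n)
    out["kappa"] = (out["pcc"] - pe) / (1 - pe) if pe < 1 else math.nan
    d = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["mcc"] = (tp * tn - fp * fn) / d if d else math.nan
    out["tss"] = out["sens"] + out["spec"] - 1
    return out


class TestConfusion:
    def test_hand_tabulation(self):
        cm = confusion([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1], 0.5)
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 1)

    def test_zero_threshold_has_no_missed_presences(self):
        rng = np.random.default_rng(0)
        cm = confusion(rng.integers(0, 2, 50), rng.uniform(size=50), 0.0)
        assert cm.fn == 0

    def test_threshold_above_max_predicts_nothing(self):
        cm = confusion([1, 0, 1], [0.2, 0.5, 0.9], 1.5)
        assert cm.tp == 0 and cm.fp == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [], 0.5)


class TestScores:
    def test_perfect_agreement_gives_unit_tss_and_kappa(self):
        cm = confusion([1, 1, 0, 0], [1.0, 1.0, 0.0, 0.0], 0.5)
        s = scores_from_confusion(cm)
        assert s.tss == pytest.approx(1.0)
        assert s.kappa == pytest.approx(1.0)

    def test_frozen_hand_computed_case(self):
        s = scores_from_confusion(ConfusionMatrix(tp=40, fp=10, fn=5, tn=45))
        assert s.sens == pytest.approx(0.889, abs=5e-4)
        assert s.spec == pytest.approx(0.818, abs=5e-4)
        assert s.pcc == pytest.approx(0.85, abs=5e-4)
        assert s.tss == pytest.approx(0.707, abs=5e-4)

    def test_random_predictions_drive_kappa_to_zero(self):
        rng = np.random.default_rng(1)
        obs = rng.integers(0, 2, 20_000)
        scores = rng.uniform(size=20_000)
        s = scores_from_confusion(confusion(obs, scores, 0.5))
        assert abs(s.kappa) < 0.03

    def test_single_class_input_flags_kappa_and_mcc(self):
        s = scores_from_confusion(ConfusionMatrix(tp=10, fp=0, fn=0, tn=0))
        assert math.isnan(s.kappa)
        assert math.isnan(s.mcc)

    @given(
        st.tuples(
            st.integers(0, 200), st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
        ).filter(lambda t: sum(t) > 0)
    )
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_naive_reimplementation(self, counts):
        tp, fp, fn, tn = counts
        s = scores_from_confusion(ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn))
        expected = naive_scores(tp, fp, fn, tn)
        for key, val in expected.items():
            got = getattr(s, key)
            if math.isnan(val):
                assert math.isnan(got), key
            else:
                assert got == pytest.approx(val, abs=1e-12), key

    def test_mcc_symmetric_under_class_swap(self):
        s = scores_from_confusion(ConfusionMatrix(tp=40, fp=10, fn=5, tn=45))
        swapped = scores_from_confusion(ConfusionMatrix(tp=45, fp=5, fn=10, tn=40))
        assert s.mcc == pytest.approx(swapped.mcc)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_tie_handling_matches_pair_counting(self):
        obs = np.array([1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.5, 0.5, 0.3, 0.1])
        wins = half = 0
        for i in np.flatnonzero(obs):
            for j in np.flatnonzero(~obs.astype(bool)):
                if scores[i] > scores[j]:
                    wins += 1
                elif scores[i] == scores[j]:
                    half += 1
        expected = (wins + 0.5 * half) / (obs.sum() * (len(obs) - obs.sum()))
        assert auc(obs, scores) == pytest.approx(expected)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        obs = rng.integers(0, 2, 200)
        obs[:5], obs[5:10] = 1, 0
        scores = rng.uniform(size=200)
        assert auc(obs, scores) == pytest.approx(auc(obs, np.exp(5 * scores)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.4])


class TestOptimalThreshold:
    def test_separable_scores_threshold_in_gap(self):
        th = optimal_threshold([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert 0.2 < th < 0.8

    def test_matches_exhaustive_sweep(self):
        obs = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.8, 0.7, 0.1])
        uniq = np.unique(scores)
        cands = np.concatenate([[uniq[0] - 1e-9], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1e-9]])
        best = max(
            cands,
            key=lambda t: (
                scores_from_confusion(confusion(obs, scores, t)).tss,
                -t,
            ),
        )
        assert optimal_threshold(obs, scores) == pytest.approx(best)

    def test_tss_criterion_equals_roc_criterion(self):
        rng = np.random.default_rng(3)
        obs = rng.integers(0, 2, 100)
        obs[0], obs[1] = 0, 1
        scores = rng.uniform(size=100)
        assert optimal_threshold(obs, scores, "roc") == optimal_threshold(obs, scores, "tss")


class _FakeRun:
    def __init__(self, auc_val, tss_val, species="sp"):
        from sdmcascade import EvaluationScores

        self.species = species
        self.scores = EvaluationScores(
            sens=0, spec=0, ppp=0, npp=0, pcc=0, tss=tss_val, kappa=0, mcc=0, auc=auc_val
        )


class TestFilterRuns:
    def test_inclusive_boundaries_pass(self):
        assert len(filter_runs([_FakeRun(0.85, 0.75)])) == 1

    def test_dual_conjunction_fails_on_one_low_score(self):
        assert filter_runs([_FakeRun(0.86, 0.74)]) == []
        assert filter_runs([_FakeRun(0.84, 0.80)]) == []

    def test_species_override_tightens_roc(self):
        runs = [_FakeRun(0.88, 0.80, species="quercus_rp")]
        assert filter_runs(runs, roc_overrides={"quercus_rp": 0.90}) == []
        assert len(filter_runs(runs)) == 1


class TestPermutationImportance:
    def test_ignored_predictor_has_zero_importance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 3))

        def predict(Z):  # linear model with zero weight on column 2
            return 1 / (1 + np.exp(-(Z[:, 0] + 0.5 * Z[:, 1])))

        imp = permutation_importance(predict, X, ["a", "b", "c"], n_permutations=2, seed=0)
        assert imp["c"] == 0.0
        assert imp["a"] > imp["c"]

    def test_constant_prediction_flagged_nan(self):
        X = np.random.default_rng(5).normal(size=(50, 2))
        imp = permutation_importance(lambda Z: np.full(len(Z), 0.5), X, ["a", "b"], seed=0)
        assert imp.isna().all()

    def test_standardized_importances_sum_to_hundred(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))

        def predict(Z):
            return 1 / (1 + np.exp(-(Z[:, 0] - Z[:, 2])))

        imp = permutation_importance(predict, X, ["a", "b", "c"], n_permutations=2, seed=1)
        assert imp.sum() == pytest.approx(100.0)
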