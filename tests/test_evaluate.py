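"""Metrics, grouped CV splitting, behavior summaries and pipeline reports."""

import math

import numpy as np
import pytest

from ethoclock.core import BehaviorCatalog, PhaseSchedule
from ethoclock.evaluate import (
    Protocol,
    behavior_summary,
    block_kfold,
    block_split,
    confusion_counts,
    evaluate_pipeline,
    roc_auc,
    sensitivity_specificity,
)
from ethoclock.tabular import ModelSpec
from ethoclock.windows import aggregate_samples, build_windows
from .conftest import make_stream


def brute_force_auc(y, s):
    """All-pairs rank statistic: P(s_pos > s_neg) + 0.5 P(equal)."""
    pos = s[y == 1]
    neg = s[y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestBlockKfold:
    def test_ten_blocks_five_folds_two_each(self):
        folds = block_kfold(50, k=5, block_len=5, seed=0)
        for _, test in folds:
            assert test.size == 10

    def test_test_folds_partition_all_windows(self):
        folds = block_kfold(47, k=5, block_len=3, seed=1)
        all_test = np.concatenate([t for _, t in folds])
        assert np.array_equal(np.sort(all_test), np.arange(47))
        for tr, te in folds:
            assert np.intersect1d(tr, te).size == 0

    def test_blocks_never_straddle_the_split(self):
        folds = block_kfold(60, k=3, block_len=4, seed=2)
        for _, te in folds:
            blocks = np.unique(te // 4)
            expanded = np.concatenate([np.arange(b * 4, b * 4 + 4) for b in blocks])
            assert np.array_equal(np.sort(te), np.sort(expanded))

    def test_block_split_fracs(self):
        tune, train, test = block_split(100, (0.2, 0.5, 0.3), block_len=5, seed=0)
        assert len(tune) == 20 and len(train) == 50 and len(test) == 30
        assert np.array_equal(
            np.sort(np.concatenate([tune, train, test])), np.arange(100)
        )


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_counts([0, 1, 0, 1], [0, 1, 0, 1])
        assert cm[0, 1] == cm[1, 0] == 0

    def test_single_day_to_night_error(self):
        cm = confusion_counts([0, 0, 1, 1], [0, 1, 1, 1])
        assert cm[0, 1] == 1 and cm[0, 0] == 1 and cm[1, 1] == 2

    def test_counts_sum_and_accuracy_identity(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        cm = confusion_counts(y, p)
        assert cm.sum() == 200
        assert np.trace(cm) / 200 == pytest.approx(float(np.mean(y == p)))


class TestRocAuc:
    def test_perfect_separation(self):
        _, a = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert a == 1.0

    def test_one_win_one_loss_pair(self):
        # positives score 0.9 and 0.6 against the negative's 0.7
        _, a = roc_auc([1, 1, 0], [0.9, 0.6, 0.7])
        assert a == 0.5

    def test_constant_scores_are_chance(self):
        _, a = roc_auc([0, 1, 0, 1], [0.4] * 4)
        assert a == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    def test_equals_pairwise_rank_statistic(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        s = np.round(rng.random(60), 2)  # duplicates force tie handling
        _, a = roc_auc(y, s)
        assert a == pytest.approx(brute_force_auc(y, s), abs=1e-12)


class TestSensitivitySpecificity:
    def test_perfect(self):
        assert sensitivity_specificity(np.array([[5, 0], [0, 7]])) == (1.0, 1.0)

    def test_all_predicted_positive(self):
        sens, spec = sensitivity_specificity(np.array([[0, 4], [0, 6]]))
        assert (sens, spec) == (1.0, 0.0)

    def test_reported_ratio_example(self):
        cm = np.array([[97, 3], [16, 84]])  # rows: true day, true night
        sens, spec = sensitivity_specificity(cm, positive_class=1)
        assert (sens, spec) == (0.84, 0.97)

    def test_zero_denominator_flags_nan(self):
        sens, _ = sensitivity_specificity(np.array([[3, 1], [0, 0]]))
        assert math.isnan(sens)


class TestBehaviorSummary:
    def test_identical_phases_give_unit_pvalues(self):
        # day and night each see the same two window variants -> equal means
        cat = BehaviorCatalog(("A", "B"))
        sched = PhaseSchedule(day_len_s=600.0, night_len_s=600.0)
        rows = []
        t = 0.0
        for _ in range(8):  # 4 full cycles of [variant1, variant2] x phases
            for a_dur in (200.0, 100.0):
                rows.append((0, t, a_dur))
                rows.append((1, t + a_dur, 300.0 - a_dur))
                t += 300.0
        stream = make_stream(cat, rows)
        samples = aggregate_samples(stream, fps=10, frames_per_sample=30)
        summ = behavior_summary(samples, sched, window_len=100)
        assert np.allclose(summ.table["p_value"], 1.0)

    def test_window_durations_conserve_span(self, day1_calibrated_stream):
        cfg, stream = day1_calibrated_stream
        samples = aggregate_samples(stream, cfg.fps)
        summ = behavior_summary(samples, cfg.schedule, stream=stream)
        assert summ.table["day_mean_s"].sum() == pytest.approx(300.0, abs=0.01)
        assert summ.table["night_mean_s"].sum() == pytest.approx(300.0, abs=0.01)

    def test_calibrated_phases_separate_many_behaviors(self, day1_calibrated_stream):
        """Well over 20 activities differ between day and night at p < 0.001."""
        cfg, stream = day1_calibrated_stream
        samples = aggregate_samples(stream, cfg.fps)
        summ = behavior_summary(samples, cfg.schedule, stream=stream)
        assert int((summ.table["p_value"] < 1e-3).sum()) > 20
        assert summ.bout_counts is not None
        assert summ.bout_counts["night"][0] > summ.bout_counts["day"][0]


@pytest.fixture(scope="module")
def day1_windows(day1_calibrated_stream):
    cfg, stream = day1_calibrated_stream
    samples = aggregate_samples(stream, cfg.fps)
    return build_windows(samples, cfg.schedule, window_len=100, stride=100)


class TestEvaluatePipeline:
    def test_reports_are_consistent_and_reproducible(self, day1_windows):
        models = {
            "logistic": None,
            "forest": None,
            "svm": ModelSpec.svm(gamma=0.01),
            "ensemble": None,
        }
        proto = Protocol(k=5, seed=13)
        reps1 = evaluate_pipeline(day1_windows, models, proto)
        reps2 = evaluate_pipeline(day1_windows, models, proto)
        for name, r in reps1.items():
            assert r.confusion.sum() == r.n_windows
            assert 0.0 <= r.auc <= 1.0
            assert len(r.fold_accuracy) == 5
            assert r.accuracy_mean == reps2[name].accuracy_mean
            assert r.provenance == reps2[name].provenance

    def test_ensemble_requires_all_members(self, day1_windows):
        with pytest.raises(ValueError, match="ensemble"):
            evaluate_pipeline(day1_windows, {"logistic": None, "ensemble": None})

    def test_empty_selection_rejected(self, day1_windows):
        with pytest.raises(ValueError, match="no models"):
            evaluate_pipeline(day1_windows, {})

    def test_unknown_model_rejected(self, day1_windows):
        with pytest.raises(ValueError, match="unknown"):
            evaluate_pipeline(day1_windows, {"perceptron": None})
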