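"""LOPO protocol: leakage freedom, metric identities, case/model selection,
permutation importance, and classification of mixed periods."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gaitcontext.classification import (
    LeakageError,
    MetricsReport,
    classify,
    compute_metrics,
    make_classifier,
    permutation_importance,
    pure_context_rows,
    select_case,
    select_model,
    train_lopo,
)
from gaitcontext.config import CohortConfig, ContextProfile
from gaitcontext.features import FEATURE_COLUMNS
from gaitcontext.synthetic import feature_table_from_truth, generate_cohort


def separable_table(n_participants=4, n_rows=15, seed=0):
    """Linearly separable toy features: duration alone separates classes."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        for j in range(n_rows):
            indoor = j % 2 == 0
            rows.append(
                {
                    "participant_id": f"P{i:02d}",
                    "period_id": f"P{i:02d}_{j:04d}",
                    "duration_min": rng.uniform(1, 3) if indoor
                    else rng.uniform(9, 14),
                    "continuity_pct": rng.uniform(50, 95),
                    "mean_norm_stride_freq": rng.uniform(0.25, 0.35),
                    "sd_norm_stride_freq": rng.uniform(0.005, 0.02),
                    "n_strides": 50,
                    "label": "indoor" if indoor else "outdoor",
                }
            )
    return pd.DataFrame(rows)


class TestMetrics:
    def test_confusion_identities(self):
        y_true = ["indoor"] * 9 + ["outdoor"] * 3
        y_pred = (["indoor"] * 8 + ["outdoor"]          # 8 TP, 1 FN
                  + ["indoor"] + ["outdoor"] * 2)       # 1 FP, 2 TN
        m = compute_metrics(y_true, y_pred)
        assert (m.tp, m.fp, m.tn, m.fn) == (8, 1, 2, 1)
        assert m.accuracy == pytest.approx(10 / 12)
        assert m.f1 == pytest.approx(16 / 18)

    def test_single_class_auroc_undefined(self):
        m = compute_metrics(["indoor"] * 5, ["indoor"] * 5,
                            scores=np.linspace(0, 1, 5))
        assert m.auroc is None

    def test_random_scorer_auroc_near_half(self):
        """A random score on balanced labels averages AUROC 0.5 over 50
        seeds."""
        aurocs = []
        for s in range(50):
            rng = np.random.default_rng(s)
            y = np.array(["indoor", "outdoor"] * 50)
            m = compute_metrics(y, y, scores=rng.uniform(size=100))
            aurocs.append(m.auroc)
        assert np.mean(aurocs) == pytest.approx(0.5, abs=0.05)


class TestTrainLopo:
    @pytest.mark.parametrize("algorithm", ["random_forest", "ensemble_svm"])
    def test_separable_case_perfect_folds(self, algorithm):
        table = separable_table()
        bundle = train_lopo(table, algorithm, seed=0)
        assert all(f.metrics.accuracy == 1.0 for f in bundle.folds)

    def test_one_fold_per_participant_no_leakage(self, midsize_truth_features):
        cohort, table = midsize_truth_features
        pool = pure_context_rows(table)
        bundle = train_lopo(pool, "random_forest", seed=3)
        held = [f.held_out for f in bundle.folds]
        assert sorted(held) == sorted(pool["participant_id"].unique())

    def test_recovery_accuracy_on_synthetic_cohort(self, midsize_truth_features):
        """With the configured class separation a random forest achieves
        >= 0.85 average LOPO validation accuracy."""
        _, table = midsize_truth_features
        bundle = train_lopo(table, "random_forest", seed=5)
        assert bundle.avg_accuracy >= 0.85

    def test_permuted_labels_auroc_near_chance(self, midsize_truth_features):
        _, table = midsize_truth_features
        rng = np.random.default_rng(12)
        shuffled = pure_context_rows(table).copy()
        shuffled["label"] = rng.permutation(shuffled["label"].to_numpy())
        bundle = train_lopo(shuffled, "random_forest", seed=12)
        assert bundle.avg_auroc == pytest.approx(0.5, abs=0.1)

    def test_reproducible_with_fixed_seed(self):
        table = separable_table(seed=4)
        b1 = train_lopo(table, "random_forest", seed=9)
        b2 = train_lopo(table, "random_forest", seed=9)
        assert b1.summary() == b2.summary()

    def test_rejects_single_participant(self):
        table = separable_table(n_participants=1)
        with pytest.raises(ValueError):
            train_lopo(table, "random_forest")


def _bundle_with(acc, f1, auroc, algorithm="random_forest"):
    model = make_classifier(algorithm, seed=0)
    m = MetricsReport(acc, f1, auroc, 1, 0, 1, 0)
    from gaitcontext.classification import FoldResult, ModelBundle
    return ModelBundle(algorithm, "biomechanics",
                       [FoldResult("P00", model, m)])


class TestSelection:
    def test_dominant_case_selected(self):
        best = select_case([_bundle_with(0.90, 0.90, 0.90),
                            _bundle_with(0.88, 0.88, 0.88, "ensemble_svm")])
        assert best.avg_accuracy == 0.90

    def test_tie_breaks_by_algorithm_id(self):
        a = _bundle_with(0.9, 0.9, 0.9, "random_forest")
        b = _bundle_with(0.9, 0.9, 0.9, "ensemble_svm")
        assert select_case([a, b]).algorithm == "ensemble_svm"

    def test_single_bundle_returned(self):
        b = _bundle_with(0.7, 0.7, 0.7)
        assert select_case([b]) is b

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_case([])

    def test_best_model_is_argmax_on_test_set(self, midsize_truth_features):
        _, table = midsize_truth_features
        pids = sorted(table["participant_id"].unique())
        pool = table[table["participant_id"].isin(pids[:8])]
        test = table[table["participant_id"].isin(pids[8:])]
        bundle = train_lopo(pure_context_rows(pool), "random_forest", seed=2)
        fold, metrics, per_model = select_model(bundle, test)
        assert metrics.accuracy == per_model["accuracy"].max()

    def test_selection_deterministic(self, midsize_truth_features):
        _, table = midsize_truth_features
        pids = sorted(table["participant_id"].unique())
        pool = table[table["participant_id"].isin(pids[:8])]
        test = table[table["participant_id"].isin(pids[8:])]
        bundle = train_lopo(pure_context_rows(pool), "random_forest", seed=2)
        f1, _, _ = select_model(bundle, test)
        f2, _, _ = select_model(bundle, test)
        assert f1.held_out == f2.held_out

    def test_overlapping_test_participants_raise(self):
        table = separable_table()
        bundle = train_lopo(table, "random_forest", seed=0)
        with pytest.raises(LeakageError):
            select_model(bundle, table)


class TestPermutationImportance:
    def test_null_feature_importance_near_zero(self):
        table = separable_table(n_participants=6, n_rows=20, seed=1)
        rng = np.random.default_rng(5)
        table = table.copy()
        table["noise_feature"] = rng.normal(size=len(table))
        cols = FEATURE_COLUMNS + ["noise_feature"]
        model = make_classifier("random_forest", seed=0)
        model.fit(table[cols].to_numpy(), table["label"].to_numpy())
        imp = permutation_importance(model, table, n_repeats=20, seed=0,
                                     feature_columns=cols)
        null_row = imp[imp["feature"] == "noise_feature"].iloc[0]
        assert abs(null_row["importance_mean"]) <= 0.02

    def test_duration_dominates_when_only_duration_separates(self):
        """A cohort whose classes share speed and continuity distributions
        but differ in duration must rank duration first."""
        indoor = ContextProfile("indoor", duration_mean_min=2.2,
                                interruption_rate_per_min=0.5,
                                stride_speed_mean_ms=1.2,
                                stride_speed_sd_ms=0.3,
                                period_count_weight=0.5)
        outdoor = dataclasses.replace(indoor, context_label="outdoor",
                                      duration_mean_min=11.4)
        cfg = CohortConfig(indoor=indoor, outdoor=outdoor,
                           context_mix_mean=0.5,
                           mixed_fraction=0.0, unlabeled_fraction=0.0)
        cohort = generate_cohort(6, 60, cfg, seed=15)
        table = feature_table_from_truth(cohort)
        model = make_classifier("random_forest", seed=1)
        model.fit(table[FEATURE_COLUMNS].to_numpy(),
                  table["label"].to_numpy())
        imp = permutation_importance(model, table, n_repeats=10, seed=1)
        assert imp.iloc[0]["feature"] == "duration_min"

    def test_single_repeat_reproducible(self):
        table = separable_table(seed=3)
        model = make_classifier("random_forest", seed=0)
        model.fit(table[FEATURE_COLUMNS].to_numpy(),
                  table["label"].to_numpy())
        i1 = permutation_importance(model, table, n_repeats=1, seed=8)
        i2 = permutation_importance(model, table, n_repeats=1, seed=8)
        pd.testing.assert_frame_equal(i1, i2)


class TestClassify:
    def test_training_rows_recover_their_labels(self):
        table = separable_table(seed=2)
        model = make_classifier("random_forest", seed=0)
        model.fit(table[FEATURE_COLUMNS].to_numpy(),
                  table["label"].to_numpy())
        out = classify(model, table)
        assert (out["predicted_label"] == table["label"]).all()

    @pytest.mark.parametrize("algorithm", ["random_forest", "ensemble_svm"])
    def test_scores_within_unit_interval(self, algorithm):
        table = separable_table(seed=2)
        model = make_classifier(algorithm, seed=0)
        model.fit(table[FEATURE_COLUMNS].to_numpy(),
                  table["label"].to_numpy())
        out = classify(model, table)
        assert out["score_indoor"].between(0, 1).all()

    def test_missing_feature_column_raises(self):
        table = separable_table().drop(columns=["duration_min"])
        model = make_classifier("random_forest", seed=0)
        with pytest.raises(KeyError):
            classify(model, table)

    def test_mixed_periods_follow_majority_segment(self):
        """Mixed walks built as majority/minority concatenations are
        classified to the majority context in >= 70% of cases."""
        cfg = CohortConfig(mixed_fraction=0.3, unlabeled_fraction=0.0,
                           context_mix_mean=0.6)
        cohort = generate_cohort(10, 40, cfg, seed=23)
        table = feature_table_from_truth(cohort)
        pure = pure_context_rows(table)
        mixed = table[table["label"] == "mixed"]
        assert len(mixed) >= 50
        model = make_classifier("random_forest", seed=0)
        model.fit(pure[FEATURE_COLUMNS].to_numpy(),
                  pure["label"].to_numpy())
        out = classify(model, mixed)
        agree = (out["predicted_label"] == mixed["majority_context"]).mean()
        assert agree >= 0.70
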