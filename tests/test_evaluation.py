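import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hbvision.corridor_decision import CorridorLabel
from hbvision.evaluation import (
    aggregate_predictions,
    corridor_confusion,
    f1_scores,
    make_grouped_folds,
    regression_metrics,
    run_grouped_cv,
    type_error_rates,
)
from hbvision.pipeline import quick_histogram_features
from hbvision.synthetic_data import (
    CohortConfig,
    RenderParams,
    cohort_to_frame,
    generate_cohort,
)

from conftest import tiny_subgroups

R, Y, G = CorridorLabel.RED, CorridorLabel.YELLOW, CorridorLabel.GREEN


class TestMakeGroupedFolds:
    def test_even_split(self):
        plan = make_grouped_folds([f"P{i}" for i in range(20)], k=10, seed=0)
        sizes = [len(plan.patients_in_fold(f)) for f in range(10)]
        assert sizes == [2] * 10

    def test_sizes_differ_by_at_most_one(self):
        plan = make_grouped_folds([f"P{i}" for i in range(23)], k=10, seed=1)
        sizes = [len(plan.patients_in_fold(f)) for f in range(10)]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 23

    def test_every_patient_exactly_one_fold(self):
        ids = [f"P{i}" for i in range(37)]
        plan = make_grouped_folds(ids, k=10, seed=2)
        assert set(plan.assignment) == set(ids)

    def test_deterministic(self):
        ids = [f"P{i}" for i in range(15)]
        a = make_grouped_folds(ids, k=5, seed=3)
        b = make_grouped_folds(ids, k=5, seed=3)
        assert a.assignment == b.assignment

    def test_repeated_ids_collapse(self):
        plan = make_grouped_folds(["A", "A", "B", "C", "B"], k=3, seed=0)
        assert set(plan.assignment) == {"A", "B", "C"}

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_grouped_folds(["A", "B"], k=10, seed=0)


class TestAggregatePredictions:
    def test_odd_count_median(self):
        assert aggregate_predictions([5.0, 5.2, 6.4]) == 5.2

    def test_even_count_mean_of_central(self):
        assert aggregate_predictions([5.0, 6.0]) == 5.5

    def test_outlier_robust(self):
        assert aggregate_predictions([5.0, 5.0, 99.0]) == 5.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_predictions([])

    @given(st.lists(st.floats(min_value=1.0, max_value=15.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_median_between_min_and_max(self, preds):
        agg = aggregate_predictions(preds)
        assert min(preds) <= agg <= max(preds)


class TestRegressionMetrics:
    def test_perfect_predictions(self):
        metrics = regression_metrics([4.0, 6.0, 8.0], [4.0, 6.0, 8.0])
        assert metrics == {"residual_sd": 0.0, "mse": 0.0, "r2": 1.0}

    def test_hand_computed_toy(self):
        metrics = regression_metrics([4.0, 6.0, 8.0], [5.0, 6.0, 7.0])
        assert metrics["mse"] == pytest.approx(2 / 3)
        assert metrics["r2"] == pytest.approx(0.75)
        assert metrics["residual_sd"] == pytest.approx(1.0)

    def test_constant_mean_prediction_r2_zero(self):
        y = np.array([4.0, 6.0, 8.0])
        metrics = regression_metrics(y, np.full(3, y.mean()))
        assert metrics["r2"] == pytest.approx(0.0)

    def test_constant_truth_undefined(self):
        with pytest.raises(ValueError):
            regression_metrics([5.0, 5.0, 5.0], [4.0, 5.0, 6.0])

    def test_negative_r2_not_clipped(self):
        metrics = regression_metrics([4.0, 6.0, 8.0], [10.0, 2.0, 12.0])
        assert metrics["r2"] < 0

    def test_permutation_invariance(self, rng):
        y_true = rng.normal(7, 1.5, 50)
        y_pred = y_true + rng.normal(0, 0.5, 50)
        perm = rng.permutation(50)
        a = regression_metrics(y_true, y_pred)
        b = regression_metrics(y_true[perm], y_pred[perm])
        for key in a:
            assert a[key] == pytest.approx(b[key])


class TestCorridorConfusion:
    def test_fig_counts_total_23(self):
        true = [R] * 3 + [Y] * 23 + [G] * 19
        pred = [R] * 3 + [Y] * 7 + [R] * 15 + [G] * 1 + [G] * 13 + [Y] * 6
        summary = corridor_confusion(true, pred)
        assert summary["total_correct"] == 23
        assert summary["total"] == 45
        expected = np.array([[3, 0, 0], [15, 7, 1], [0, 6, 13]])
        np.testing.assert_array_equal(summary["confusion"], expected)

    def test_all_correct(self):
        labels = [R, Y, G, G]
        summary = corridor_confusion(labels, labels)
        assert summary["per_class_accuracy"] == {"Red": 1.0, "Yellow": 1.0, "Green": 1.0}
        assert np.trace(summary["confusion"]) == 4

    def test_empty_input(self):
        summary = corridor_confusion([], [])
        np.testing.assert_array_equal(summary["confusion"], np.zeros((3, 3), int))

    def test_string_labels(self):
        summary = corridor_confusion(["Red", "Green"], ["Red", "Yellow"])
        assert summary["total_correct"] == 1


class TestTypeErrorRates:
    def test_all_in_corridor(self):
        hb = [4.0, 5.0, 7.0]
        rates = type_error_rates(hb, hb)
        assert rates["type1"] == 0.0
        assert rates["type2"]["Red"] == 0.0
        assert rates["type2"]["Yellow"] == 0.0

    def test_one_in_ten_red_predicted_green(self):
        measured = [4.0] * 10
        predicted = [7.0] + [4.0] * 9
        rates = type_error_rates(measured, predicted)
        assert rates["type1"] == pytest.approx(0.1)
        assert rates["type2"]["Red"] == pytest.approx(0.1)

    def test_no_true_red_gives_absent_rate(self):
        rates = type_error_rates([5.0, 7.0], [5.0, 7.0])
        assert rates["type1"] is None
        assert rates["type2"]["Red"] is None

    def test_yellow_predicted_green_counts_as_type2(self):
        rates = type_error_rates([5.0, 5.0], [7.0, 5.0])
        assert rates["type2"]["Yellow"] == pytest.approx(0.5)

    def test_green_cannot_have_type2(self):
        rates = type_error_rates([7.0, 8.0], [4.0, 5.0])
        assert rates["type2"]["Green"] == 0.0


class TestF1Scores:
    def test_perfect_three_class(self):
        labels = [R, Y, G, R, Y, G]
        scores = f1_scores(labels, labels)
        assert scores["f1_macro"] == 1.0
        assert scores["f1_weighted"] == 1.0

    def test_never_predicted_class_zero(self):
        scores = f1_scores([R, G], [G, G])
        assert scores["per_class"]["Red"] == 0.0

    def test_hand_computed_two_class_toy(self):
        true = [R, R, G, G]
        pred = [R, G, G, G]
        scores = f1_scores(true, pred)
        assert scores["per_class"]["Red"] == pytest.approx(2 / 3)
        assert scores["per_class"]["Green"] == pytest.approx(0.8)
        assert scores["f1_macro"] == pytest.approx((2 / 3 + 0.8) / 2)
        assert scores["f1_weighted"] == pytest.approx((2 * 2 / 3 + 2 * 0.8) / 4)


def _quick_benchmark(seed=0, slope=3.75, n=(30, 20, 30)):
    cfg = CohortConfig(subgroups=tiny_subgroups(*n), seed=seed)
    entries = cohort_to_frame(generate_cohort(cfg))
    render = RenderParams(
        eyelid_images=1, fingernail_images=1, hue_slope=slope, pixel_hue_noise_sd=4.0
    )
    features = quick_histogram_features(entries, render, seed=seed + 1000)
    return features, entries


class TestRunGroupedCv:
    def test_leakage_audit_and_grouping(self):
        features, entries = _quick_benchmark()
        predictions, report = run_grouped_cv(
            features, entries, modality="eyelid", family="ridge", k=5, seed=0,
            n_components=4,
        )
        assert report.n_entries == len(entries)
        # every (patient, visit) in exactly one fold; all its rows share it
        folds = predictions.groupby("patient_id")["fold"].nunique()
        assert (folds == 1).all()

    def test_signal_recovered_on_strong_link(self):
        features, entries = _quick_benchmark()
        _, report = run_grouped_cv(
            features, entries, modality="combined", family="ridge", k=5, seed=0,
            n_components=4,
        )
        assert report.pooled["r2"] > 0.5

    def test_null_signal_control_five_seeds(self):
        # hue-Hb slope 0: cross-validated pooled R2 within [-0.15, 0.15];
        # full-size cohort (>= 400 entries) per the stated control setup
        for seed in range(5):
            entries = cohort_to_frame(generate_cohort(CohortConfig(seed=seed)))
            render = RenderParams(
                eyelid_images=1, fingernail_images=1, hue_slope=0.0,
                pixel_hue_noise_sd=4.0,
            )
            features = quick_histogram_features(entries, render, seed=seed + 1000)
            _, report = run_grouped_cv(
                features, entries, modality="combined", family="gbm", k=10,
                seed=seed, n_components=4,
            )
            assert -0.15 <= report.pooled["r2"] <= 0.15

    def test_deterministic(self):
        features, entries = _quick_benchmark()
        a, _ = run_grouped_cv(features, entries, modality="eyelid", family="gbm",
                              k=5, seed=1, n_components=4)
        b, _ = run_grouped_cv(features, entries, modality="eyelid", family="gbm",
                              k=5, seed=1, n_components=4)
        pd.testing.assert_frame_equal(a, b)

    def test_fold_metrics_persisted(self):
        features, entries = _quick_benchmark()
        _, report = run_grouped_cv(features, entries, modality="eyelid",
                                   family="ridge", k=5, seed=0, n_components=4)
        assert len(report.fold_metrics) == 5
        assert set(report.mean_over_folds) == {"residual_sd", "mse", "r2"}
        assert report.pooled["r2"] is not None

    def test_classification_task(self):
        features, entries = _quick_benchmark()
        predictions, report = run_grouped_cv(
            features, entries, modality="eyelid", family="ridge",
            task="classification", k=5, seed=0, n_components=4,
        )
        assert "pred_label" in predictions.columns
        assert 0.0 <= report.f1["f1_weighted"] <= 1.0
        assert report.confusion.sum() == len(predictions)

    def test_combined_requires_both_modalities(self):
        features, entries = _quick_benchmark()
        only_eyelid = features[features["modality"] == "eyelid"]
        with pytest.raises(ValueError):
            run_grouped_cv(only_eyelid, entries, modality="combined",
                           family="ridge", k=5, seed=0, n_components=4)

    def test_unknown_arm_rejected(self):
        features, entries = _quick_benchmark()
        with pytest.raises(ValueError):
            run_grouped_cv(features, entries, modality="both", k=5)
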