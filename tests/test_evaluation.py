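"""Confusion metrics, ROC/AUC and the leave-one-animal-out loop."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from eegcbf.evaluation import (
    ConfusionMatrix,
    confusion,
    evaluate_all,
    f1_score,
    make_loao_folds,
    metrics,
    roc_auc,
)
from eegcbf.models import ClassifierSpec

from test_io import make_table


class TestConfusion:
    def test_perfect_agreement(self):
        cm = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        cm = confusion([1, 0], [1, 1])
        assert (cm.tp, cm.fp) == (1, 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no predictions"):
            confusion([], [])

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="lengths"):
            confusion([1, 0], [1])

    def test_non_binary_labels(self):
        with pytest.raises(ValueError, match="0/1"):
            confusion([1, 2], [1, 0])

    def test_total_invariant(self, rng):
        y = rng.integers(0, 2, 50)
        p = rng.integers(0, 2, 50)
        assert confusion(y, p).total == 50


class TestMetrics:
    def test_symmetric_case(self):
        m = metrics(ConfusionMatrix(tp=8, tn=8, fp=2, fn=2))
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.8)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.8)

    def test_perfect_classifier(self):
        m = metrics(ConfusionMatrix(tp=5, tn=5, fp=0, fn=0))
        assert (m.accuracy, m.sensitivity, m.specificity, m.precision, m.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_f1_harmonic_mean_of_published_operating_point(self):
        # precision 0.906, recall 0.807 -> F1 2pr/(p+r) ~ 0.854
        assert f1_score(0.906, 0.807) == pytest.approx(0.8537, abs=5e-4)

    def test_undefined_ratio_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            m = metrics(ConfusionMatrix(tp=0, tn=5, fp=2, fn=0))
        assert np.isnan(m.sensitivity)


class TestROC:
    def test_perfect_ordering(self):
        _, auc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_exhaustive_pair_counting_example(self):
        _, auc = roc_auc([1, 0, 1], [0.9, 0.8, 0.7])
        assert auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.2, 0.6])

    def test_curve_endpoints(self, rng):
        y = rng.integers(0, 2, 30)
        y[0], y[1] = 0, 1
        points, _ = roc_auc(y, rng.uniform(0, 1, 30))
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_auc_equals_normalized_mann_whitney_u(self, rng):
        """Trapezoidal AUC over all thresholds coincides with the
        normalized Mann-Whitney U statistic on 1,000 random instances."""
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            # ties included: scores drawn from a small discrete set
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            _, auc = roc_auc(y, scores)
            u = stats.mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
            expected = u / (np.sum(y == 1) * np.sum(y == 0))
            assert auc == pytest.approx(expected, abs=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


class TestFoldPlan:
    def test_eight_animals_eight_folds(self, feature_table):
        plan = make_loao_folds(feature_table)
        assert plan.n_folds == feature_table["animal_id"].nunique()
        for train_ids, held_out in plan.folds:
            assert held_out not in train_ids

    def test_published_cohort_fold_counts(self):
        """Holding out the mixed-class animal leaves 117 group-0 and 71
        group-1 training epochs."""
        table = make_table()
        plan = make_loao_folds(table)
        train = table[table["animal_id"] != "animal_7"]
        assert int((train["group"] == 0).sum()) == 117
        assert int((train["group"] == 1).sum()) == 71
        assert plan.n_folds == 8

    def test_single_animal_rejected(self):
        table = make_table({"a": (5, 5)})
        with pytest.raises(ValueError, match="two animals"):
            make_loao_folds(table)

    def test_single_class_training_set_rejected(self):
        table = make_table({"a": (6, 0), "b": (0, 6)})
        with pytest.raises(ValueError, match="single class"):
            make_loao_folds(table)


class TestEvaluateAll:
    @pytest.fixture(scope="class")
    def report(self, small_table):
        specs = [ClassifierSpec(k, seed=0) for k in ("LR", "KNN")]
        return evaluate_all(small_table, specs, seed=0)

    def test_pooled_confusion_covers_cohort(self, report, small_table):
        for cm in report.confusions.values():
            assert cm.total == len(small_table)

    def test_f1_identity_on_report(self, report):
        for m in report.per_model.values():
            if np.isfinite(m.precision) and np.isfinite(m.sensitivity):
                assert m.f1 == pytest.approx(f1_score(m.precision, m.sensitivity))

    def test_mean_is_arithmetic_mean(self, report):
        for name in ("accuracy", "sensitivity", "specificity", "auc"):
            vals = [getattr(m, name) for m in report.per_model.values()]
            assert getattr(report.mean_metrics, name) == pytest.approx(np.mean(vals))

    def test_report_frame_layout(self, report):
        frame = report.to_frame()
        assert list(frame.columns) == [
            "model", "accuracy", "sensitivity", "specificity", "precision", "f1", "auc",
        ]
        assert frame["model"].tolist() == ["LR", "KNN", "mean"]

    def test_no_leakage_by_construction(self, small_table):
        """Every fold's training rows exclude the held-out animal."""
        plan = make_loao_folds(small_table)
        for train_ids, held_out in plan.folds:
            rows = small_table[small_table["animal_id"].isin(train_ids)]
            assert held_out not in set(rows["animal_id"])
            assert len(rows) + (small_table["animal_id"] == held_out).sum() == len(
                small_table
            )
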