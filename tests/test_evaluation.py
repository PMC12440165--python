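"""Evaluation protocol: metric definitions, grouped CV, tests, kappa bounds."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asgbc.data import Dataset
from asgbc.evaluation import (
    METRIC_NAMES,
    RaterSummary,
    aggregate_folds,
    confusion_and_metrics,
    grouped_cross_validation,
    kappa_bounds,
    noise_robustness,
    paired_comparison,
    relative_change,
)


def sklearn_metrics(y_true, y_pred):
    """Independent reference via scikit-learn's generic metric functions."""
    from sklearn.metrics import accuracy_score, f1_score, recall_score

    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    binary_true = (y_true == 2).astype(int)
    binary_pred = (y_pred == 2).astype(int)
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "sensitivity": recall_score(binary_true, binary_pred, zero_division=0),
        "specificity": recall_score(1 - binary_true, 1 - binary_pred, zero_division=0),
        "f1_malignant": f1_score(binary_true, binary_pred, zero_division=0),
        "macro_f1": f1_score(y_true, y_pred, average="macro", labels=[0, 1, 2],
                             zero_division=0),
    }


class TestConfusionAndMetrics:
    def test_perfect_diagonal(self):
        y = np.repeat([0, 1, 2], 10)
        cm, metrics = confusion_and_metrics(y, y)
        assert np.array_equal(cm, np.diag([10, 10, 10]))
        assert all(metrics[m] == 1.0 for m in METRIC_NAMES)

    def test_hand_computed_example(self):
        # rows (true -> predicted): normal [8,2,0], benign [1,9,0], malignant [0,2,8]
        y_true = np.repeat([0, 1, 2], 10)
        y_pred = np.concatenate(
            [np.repeat([0, 1], [8, 2]), np.repeat([0, 1], [1, 9]), np.repeat([1, 2], [2, 8])]
        )
        _, metrics = confusion_and_metrics(y_true, y_pred)
        assert metrics["accuracy"] == pytest.approx(25 / 30)
        assert metrics["sensitivity"] == pytest.approx(0.8)
        assert metrics["specificity"] == pytest.approx(1.0)
        assert metrics["f1_malignant"] == pytest.approx(16 / 18)
        assert metrics["macro_f1"] == pytest.approx((16 / 19 + 18 / 23 + 16 / 18) / 3)

    def test_string_labels_accepted(self):
        _, metrics = confusion_and_metrics(
            ["normal", "malignant"], ["normal", "malignant"]
        )
        assert metrics["accuracy"] == 1.0

    def test_empty_or_unknown_rejected(self):
        with pytest.raises(ValueError):
            confusion_and_metrics([], [])
        with pytest.raises(ValueError):
            confusion_and_metrics(["normal"], ["cyst"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_matches_generic_oracle(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(3, 60))
        y_true = gen.integers(0, 3, n)
        y_pred = gen.integers(0, 3, n)
        _, metrics = confusion_and_metrics(y_true, y_pred)
        reference = sklearn_metrics(y_true, y_pred)
        for m in METRIC_NAMES:
            assert metrics[m] == pytest.approx(reference[m], abs=1e-12), m


class TestGroupedCV:
    def make_dataset(self, n_patients, images_each=3, seed=0):
        gen = np.random.default_rng(seed)
        import pandas as pd

        rows = []
        for p in range(n_patients):
            label = ["normal", "benign", "malignant"][p % 3]
            for _ in range(images_each):
                rows.append({"patient_id": f"p{p:03d}", "label": label})
        manifest = pd.DataFrame(rows)
        images = gen.random((len(manifest), 8, 8))
        return Dataset(images, manifest)

    @staticmethod
    def majority_pipeline(train_ds, val_ds):
        values, counts = np.unique(train_ds.labels, return_counts=True)
        return np.full(len(val_ds.images), values[counts.argmax()])

    def test_single_patient_folds(self):
        ds = self.make_dataset(10)
        seen = []

        def spy(train_ds, val_ds):
            seen.append(set(val_ds.patient_ids))
            return self.majority_pipeline(train_ds, val_ds)

        grouped_cross_validation(ds, spy, folds=10)
        assert all(len(s) == 1 for s in seen)

    def test_no_patient_leaks_across_folds(self):
        ds = self.make_dataset(30)
        overlaps = []

        def spy(train_ds, val_ds):
            overlaps.append(set(train_ds.patient_ids) & set(val_ds.patient_ids))
            return self.majority_pipeline(train_ds, val_ds)

        report = grouped_cross_validation(ds, spy, folds=10)
        assert all(not o for o in overlaps)
        assert all(len(report.per_fold[m]) == 10 for m in METRIC_NAMES)

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_cross_validation(self.make_dataset(5), self.majority_pipeline, folds=10)

    def test_csv_export_round_trips_summary(self, tmp_path):
        from asgbc.evaluation import report_to_frame
        import pandas as pd

        report = aggregate_folds(
            [{m: v for m in METRIC_NAMES} for v in (0.8, 0.9, 0.7)]
        )
        frame = report_to_frame(report)
        path = tmp_path / "summary.csv"
        frame.to_csv(path, index=False)
        loaded = pd.read_csv(path)
        assert set(loaded["metric"]) == set(METRIC_NAMES)
        row = loaded.set_index("metric").loc["accuracy"]
        assert row["mean"] == pytest.approx(0.8)

    def test_ci_formula(self):
        report = aggregate_folds(
            [{m: v for m in METRIC_NAMES} for v in (0.8, 0.9, 0.7, 0.85, 0.75)]
        )
        mean, sd = report.mean("accuracy"), report.sd("accuracy")
        lo, hi = report.ci95("accuracy")
        assert hi - mean == pytest.approx(1.96 * sd / np.sqrt(5))
        assert mean - lo == pytest.approx(1.96 * sd / np.sqrt(5))


class TestPairedComparison:
    def test_identical_vectors_degenerate(self):
        out = paired_comparison([0.8, 0.9, 0.7], [0.8, 0.9, 0.7])
        assert out == {"t": 0.0, "p": 1.0, "significant": False, "degenerate": True}

    def test_constant_shift_degenerate(self):
        a = np.linspace(0.5, 0.9, 10)
        out = paired_comparison(a + 1.0, a)
        assert out["degenerate"] and out["p"] == 1.0

    def test_matches_textbook_formula(self, rng):
        a, b = rng.random(12), rng.random(12)
        d = a - b
        t_ref = d.mean() / (d.std(ddof=1) / np.sqrt(12))
        out = paired_comparison(a, b)
        assert out["t"] == pytest.approx(t_ref, abs=1e-9)
        from scipy import stats

        assert out["p"] == pytest.approx(
            2 * stats.t.sf(abs(t_ref), df=11), abs=1e-9
        )


class TestRelativeChange:
    @pytest.mark.parametrize(
        "old,new,decimals,expected,direction",
        [
            (0.826, 0.840, 1, 1.7, "improvement"),
            (0.884, 0.875, 2, 1.02, "degradation"),
            (0.750, 0.885, 1, 18.0, "improvement"),
            (0.5, 0.5, 1, 0.0, "unchanged"),
        ],
    )
    def test_percentages(self, old, new, decimals, expected, direction):
        percent, sign = relative_change(old, new, decimals)
        assert percent == pytest.approx(expected)
        assert sign == direction

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            relative_change(0.0, 0.5)


class TestNoiseRobustness:
    def test_degradations_consistent_with_relative_change(self, rng):
        images = rng.random((30, 16, 16))
        y = rng.integers(0, 3, 30)

        def predictor(batch):
            # intensity-threshold rule: degrades gracefully under noise
            means = batch.mean(axis=(1, 2))
            return np.digitize(means, [0.45, 0.55])

        table = noise_robustness(predictor, images, y, levels=(0.05,), seed=0)
        assert table[0]["degradation"] == {m: 0.0 for m in METRIC_NAMES}
        clean, noisy = table[0]["metrics"], table[1]["metrics"]
        for m in METRIC_NAMES:
            if clean[m] > 0:
                expected, _ = relative_change(clean[m], noisy[m], 2)
                assert table[1]["degradation"][m] == pytest.approx(expected)


class TestKappaBounds:
    def test_perfect_raters_agree_exactly(self):
        a = RaterSummary(1.0, 1.0, 1.0, prevalence=0.3)
        assert kappa_bounds(a, a) == (1.0, 1.0)

    def test_uninformative_symmetric_raters_span_full_range(self):
        a = RaterSummary(0.5, 0.5, 0.5, prevalence=0.5)
        lo, hi = kappa_bounds(a, a)
        assert lo == pytest.approx(-1.0) and hi == pytest.approx(1.0)

    def test_mismatched_prevalence_rejected(self):
        a = RaterSummary(0.8, 0.7, 0.9, prevalence=0.3)
        b = RaterSummary(0.8, 0.7, 0.9, prevalence=0.4)
        with pytest.raises(ValueError):
            kappa_bounds(a, b)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_grid_search_over_joint_agreements(self, seed):
        """kappa is linear in the two within-class joint-agreement free
        parameters, so a grid over their feasible boxes (endpoints included)
        attains the exact extremes."""
        gen = np.random.default_rng(seed)
        prev = float(gen.uniform(0.1, 0.9))
        a = RaterSummary(0.0, float(gen.uniform(0, 1)), float(gen.uniform(0, 1)), prev)
        b = RaterSummary(0.0, float(gen.uniform(0, 1)), float(gen.uniform(0, 1)), prev)
        lo, hi = kappa_bounds(a, b)
        qa, qb = a.positive_rate, b.positive_rate
        pe = qa * qb + (1 - qa) * (1 - qb)
        pos_box = (max(0, a.sensitivity + b.sensitivity - 1), min(a.sensitivity, b.sensitivity))
        neg_box = (max(0, a.specificity + b.specificity - 1), min(a.specificity, b.specificity))
        kappas = []
        for x in np.linspace(*pos_box, 21):
            for z in np.linspace(*neg_box, 21):
                po = prev * (2 * x + 1 - a.sensitivity - b.sensitivity) + (1 - prev) * (
                    2 * z + 1 - a.specificity - b.specificity
                )
                kappas.append((po - pe) / (1 - pe))
        assert lo == pytest.approx(max(-1.0, min(kappas)), abs=1e-6)
        assert hi == pytest.approx(min(1.0, max(kappas)), abs=1e-6)
        assert -1.0 <= lo <= hi <= 1.0
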