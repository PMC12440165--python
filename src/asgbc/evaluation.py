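"""Evaluation protocol: confusion-matrix metrics, patient-grouped CV,
paired comparisons, noise robustness, printed-arithmetic relative changes,
and agreement (kappa) bounds from marginal rater summaries.

Conventions for the three-class task (normal, benign, malignant):

* accuracy is the plain three-class trace/total;
* sensitivity is malignant recall and specificity is the recall of the pooled
  non-malignant group (malignant-vs-rest binarisation);
* ``f1_malignant`` is the malignant-vs-rest F1; ``macro_f1`` is the
  unweighted mean of the three per-class F1 scores, with F1 defined as 0
  whenever precision + recall is 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import GroupKFold

from .phantom import CLASSES, corrupt_noise

__all__ = [
    "confusion_and_metrics",
    "MetricsReport",
    "aggregate_folds",
    "report_to_frame",
    "noise_table_to_frame",
    "grouped_cross_validation",
    "paired_comparison",
    "relative_change",
    "noise_robustness",
    "RaterSummary",
    "kappa_bounds",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "f1_malignant", "macro_f1")
MALIGNANT = CLASSES.index("malignant")


def _as_class_indices(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype.kind in "iu":
        if y.size and (y.min() < 0 or y.max() >= len(CLASSES)):
            raise ValueError("class index out of range")
        return y.astype(int)
    lut = {c: i for i, c in enumerate(CLASSES)}
    try:
        return np.asarray([lut[v] for v in y])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None


def confusion_and_metrics(y_true, y_pred):
    """3x3 confusion matrix (rows true, cols predicted) and the five metrics."""
    yt, yp = _as_class_indices(y_true), _as_class_indices(y_pred)
    if yt.shape != yp.shape or yt.size == 0:
        raise ValueError("label vectors must be equal-length and non-empty")
    cm = np.zeros((3, 3), dtype=int)
    np.add.at(cm, (yt, yp), 1)
    total = cm.sum()
    accuracy = np.trace(cm) / total

    tp = cm[MALIGNANT, MALIGNANT]
    fn = cm[MALIGNANT].sum() - tp
    fp = cm[:, MALIGNANT].sum() - tp
    tn = total - tp - fn - fp
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    f1_malignant = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0

    per_class_f1 = []
    for c in range(3):
        tp_c = cm[c, c]
        denom = 2 * tp_c + (cm[:, c].sum() - tp_c) + (cm[c].sum() - tp_c)
        per_class_f1.append(2 * tp_c / denom if denom else 0.0)
    metrics = {
        "accuracy": float(accuracy),
        "sensitivity": float(sensitivity),
        "specificity": float(specificity),
        "f1_malignant": float(f1_malignant),
        "macro_f1": float(np.mean(per_class_f1)),
    }
    return cm, metrics


@dataclass
class MetricsReport:
    """Per-fold metric vectors with mean, SD and normal-approximation 95% CI."""

    per_fold: dict = field(default_factory=dict)  # metric -> list of fold values

    @property
    def n_folds(self) -> int:
        return len(next(iter(self.per_fold.values()))) if self.per_fold else 0

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_fold[metric]))

    def sd(self, metric: str) -> float:
        return float(np.std(self.per_fold[metric], ddof=1))

    def ci95(self, metric: str):
        m, s = self.mean(metric), self.sd(metric)
        half = 1.96 * s / math.sqrt(self.n_folds)
        return (m - half, m + half)

    def summary(self) -> dict:
        out = {}
        for metric in self.per_fold:
            lo, hi = self.ci95(metric)
            out[metric] = {
                "mean": self.mean(metric),
                "sd": self.sd(metric),
                "ci95": [lo, hi],
                "per_fold": [float(v) for v in self.per_fold[metric]],
            }
        return out


def report_to_frame(report: "MetricsReport"):
    """Summary table (one row per metric: mean, sd, CI bounds) as a DataFrame."""
    import pandas as pd

    rows = []
    for metric in report.per_fold:
        lo, hi = report.ci95(metric)
        rows.append(
            {"metric": metric, "mean": report.mean(metric), "sd": report.sd(metric),
             "ci95_low": lo, "ci95_high": hi}
        )
    return pd.DataFrame(rows)


def noise_table_to_frame(table):
    """Noise-robustness rows (level, five metrics, degradations) as a DataFrame."""
    import pandas as pd

    rows = []
    for row in table:
        record = {"level": row["level"]}
        record.update(row["metrics"])
        record.update({f"{m}_degradation_pct": v for m, v in row["degradation"].items()})
        rows.append(record)
    return pd.DataFrame(rows)


def aggregate_folds(fold_metrics) -> MetricsReport:
    report = MetricsReport({m: [] for m in METRIC_NAMES})
    for metrics in fold_metrics:
        for m in METRIC_NAMES:
            report.per_fold[m].append(float(metrics[m]))
    return report


def grouped_cross_validation(dataset, pipeline_fn, folds: int = 10) -> MetricsReport:
    """Patient-grouped k-fold CV.

    ``pipeline_fn(train_dataset, val_dataset) -> y_pred`` trains on the fold's
    training images and predicts the validation images.  Patients (not
    images) are partitioned, so no patient contributes to both sides.
    """
    groups = dataset.patient_ids
    if len(np.unique(groups)) < folds:
        raise ValueError("fewer distinct patients than folds")
    report = MetricsReport({m: [] for m in METRIC_NAMES})
    for train_idx, val_idx in GroupKFold(n_splits=folds).split(groups, groups=groups):
        train_ds, val_ds = dataset.subset(train_idx), dataset.subset(val_idx)
        y_pred = pipeline_fn(train_ds, val_ds)
        _, metrics = confusion_and_metrics(val_ds.labels, y_pred)
        for m in METRIC_NAMES:
            report.per_fold[m].append(metrics[m])
    return report


def paired_comparison(metric_vec_a, metric_vec_b):
    """Two-sided paired t-test; returns (t, p, significant, degenerate).

    Zero-variance differences (including identical vectors) are degenerate:
    t is reported as 0, p as exactly 1, and significance as False.
    """
    a = np.asarray(metric_vec_a, dtype=np.float64)
    b = np.asarray(metric_vec_b, dtype=np.float64)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    d = a - b
    if np.std(d, ddof=1) <= 1e-12 * (1.0 + np.abs(d).max()):
        return {"t": 0.0, "p": 1.0, "significant": False, "degenerate": True}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "significant": bool(p < 0.05), "degenerate": False}


def relative_change(old_value: float, new_value: float, decimals: int = 1):
    """Percent change 100*|new-old|/old, rounded; direction reported separately.

    Reproduces the printed improvement/degradation percentages derived from
    metric pairs (e.g. 0.826 -> 0.840 is a 1.7% improvement at one decimal).
    """
    if old_value <= 0:
        raise ValueError("old_value must be positive")
    percent = round(100.0 * abs(new_value - old_value) / old_value, decimals)
    if new_value > old_value:
        direction = "improvement"
    elif new_value < old_value:
        direction = "degradation"
    else:
        direction = "unchanged"
    return percent, direction


def noise_robustness(
    predict_fn,
    images: np.ndarray,
    y_true,
    levels=(0.01, 0.05, 0.10),
    kernel_sigma: float = 5.0,
    seed: int = 0,
):
    """Re-evaluate a trained classifier under additive correlated noise.

    ``predict_fn(images) -> class indices``.  Returns a table (list of dicts):
    one row per level with the five metrics and their relative degradation
    against the clean row, each degradation computed by :func:`relative_change`
    at two decimals.
    """
    _, clean = confusion_and_metrics(y_true, predict_fn(images))
    table = [{"level": 0.0, "metrics": clean, "degradation": {m: 0.0 for m in METRIC_NAMES}}]
    for i, level in enumerate(levels):
        noisy = np.stack(
            [corrupt_noise(img, level, kernel_sigma, seed=seed + 1000 * i + j)
             for j, img in enumerate(images)]
        )
        _, metrics = confusion_and_metrics(y_true, predict_fn(noisy))
        degradation = {
            m: (relative_change(clean[m], metrics[m], decimals=2)[0] if clean[m] > 0 else 0.0)
            for m in METRIC_NAMES
        }
        table.append({"level": float(level), "metrics": metrics, "degradation": degradation})
    return table


@dataclass
class RaterSummary:
    """Marginal performance of one rater on the malignant-vs-rest task."""

    accuracy: float
    sensitivity: float
    specificity: float
    prevalence: float
    n: int = 0

    def __post_init__(self):
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")

    @property
    def positive_rate(self) -> float:
        return self.prevalence * self.sensitivity + (1 - self.prevalence) * (
            1 - self.specificity
        )


def kappa_bounds(rater_a: RaterSummary, rater_b: RaterSummary):
    """Extremal Cohen's kappa between two raters known only by their margins.

    Within each true class the joint correct/incorrect table is free up to
    Frechet bounds, which bound the observed agreement P_o; chance agreement
    P_e follows from the marginal positive rates alone.  Returns
    ``(kappa_min, kappa_max)``, clamped to [-1, 1].
    """
    if abs(rater_a.prevalence - rater_b.prevalence) > 1e-9:
        raise ValueError("raters must share one prevalence")
    pi = rater_a.prevalence

    def agree_range(p_a, p_b):
        both_lo = max(0.0, p_a + p_b - 1.0)
        both_hi = min(p_a, p_b)
        base = 1.0 - p_a - p_b  # agreement = 2*both_correct + 1 - p_a - p_b
        return 2 * both_lo + base, 2 * both_hi + base

    pos_lo, pos_hi = agree_range(rater_a.sensitivity, rater_b.sensitivity)
    neg_lo, neg_hi = agree_range(rater_a.specificity, rater_b.specificity)
    po_lo = pi * pos_lo + (1 - pi) * neg_lo
    po_hi = pi * pos_hi + (1 - pi) * neg_hi
    qa, qb = rater_a.positive_rate, rater_b.positive_rate
    pe = qa * qb + (1 - qa) * (1 - qb)
    if 1 - pe < 1e-12:
        return (1.0, 1.0) if po_hi >= 1 - 1e-12 else (-1.0, -1.0)
    k_min = (po_lo - pe) / (1 - pe)
    k_max = (po_hi - pe) / (1 - pe)
    k_min, k_max = sorted((k_min, k_max))
    return max(-1.0, k_min), min(1.0, k_max)
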