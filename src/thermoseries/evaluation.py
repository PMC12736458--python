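"""Cross-validated metrics, ROC averaging and nonparametric feature-set
comparison.

The positive class is cancer throughout.  Row order of confusion matrices
is (control, cancer), so the diagonal of the row-normalized matrix reads
(specificity, sensitivity).  Feature-set comparison over matched CV folds
uses the Friedman test plus pairwise exact Wilcoxon signed-rank tests with
no multiple-testing correction (raw p-values are reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold

from .assembly import CohortTensor

__all__ = [
    "FoldResult",
    "CVResult",
    "ComparisonReport",
    "Pipeline",
    "confusion_normalized",
    "metrics",
    "cross_validate",
    "mean_roc",
    "friedman_compare",
    "wilcoxon_pairwise",
    "compare_feature_sets",
]


class Pipeline(Protocol):
    """Contract a classifier adapter must satisfy for cross-validation."""

    def fit(self, train: CohortTensor, seed: int) -> None: ...

    def predict_scores(self, test: CohortTensor) -> np.ndarray: ...

    def predict_labels(self, test: CohortTensor) -> np.ndarray: ...


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    f1: float
    auc: float  # NaN when the truth is single-class


@dataclass(frozen=True)
class FoldResult:
    fold: int
    metrics: Metrics
    confusion: np.ndarray  # counts, rows (control, cancer)
    truth: np.ndarray
    labels: np.ndarray
    scores: np.ndarray
    subject_ids: tuple[str, ...]


@dataclass(frozen=True)
class CVResult:
    folds: tuple[FoldResult, ...]

    def metric_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accuracy": [f.metrics.accuracy for f in self.folds],
                "f1": [f.metrics.f1 for f in self.folds],
                "auc": [f.metrics.auc for f in self.folds],
            }
        )

    def summary(self) -> pd.DataFrame:
        mm = self.metric_matrix()
        return pd.DataFrame({"mean": mm.mean(), "sd": mm.std(ddof=0)})

    def mean_confusion_normalized(self) -> np.ndarray:
        return np.mean([confusion_normalized(f.confusion) for f in self.folds], axis=0)


def confusion_normalized(counts: np.ndarray) -> np.ndarray:
    """Row-normalize a 2x2 count matrix; empty rows become NaN."""
    counts = np.asarray(counts, dtype=float)
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = counts / sums
    return rates


def metrics(truth, labels, scores) -> Metrics:
    """Accuracy, positive-class F1 and trapezoidal ROC AUC."""
    truth = np.asarray(truth, dtype=int)
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    acc = float(accuracy_score(truth, labels))
    f1 = float(f1_score(truth, labels, pos_label=1, zero_division=0))
    auc = (
        float(roc_auc_score(truth, scores))
        if np.unique(truth).size > 1
        else float("nan")
    )
    return Metrics(acc, f1, auc)


def cross_validate(
    pipeline_factory,
    tensor: CohortTensor,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of a classifier adapter.

    ``pipeline_factory()`` must return a fresh :class:`Pipeline`; any
    fold-local standardization or augmentation is the adapter's own
    responsibility, keeping held-out subjects untouched.
    """
    y = tensor.labels
    if np.bincount(y, minlength=2).min() < folds:
        raise ValueError(
            f"cannot stratify {folds} folds with class counts {np.bincount(y)}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    results = []
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(y)), y)):
        train, test = tensor.subset(tr), tensor.subset(te)
        pipe = pipeline_factory()
        pipe.fit(train, seed=seed + fold)
        scores = np.asarray(pipe.predict_scores(test), dtype=float)
        labels = np.asarray(pipe.predict_labels(test), dtype=int)
        counts = confusion_matrix(test.labels, labels, labels=[0, 1])
        results.append(
            FoldResult(
                fold=fold,
                metrics=metrics(test.labels, labels, scores),
                confusion=counts,
                truth=test.labels.copy(),
                labels=labels,
                scores=scores,
                subject_ids=test.subject_ids,
            )
        )
    return CVResult(tuple(results))


def mean_roc(cv: CVResult, n_points: int = 101) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertically averaged ROC curve over folds at fixed FPR grid points.

    Returns (fpr_grid, mean_tpr, sd_tpr).
    """
    fpr_grid = np.linspace(0.0, 1.0, n_points)
    tprs = []
    for f in cv.folds:
        fpr, tpr, _ = roc_curve(f.truth, f.scores)
        tprs.append(np.interp(fpr_grid, fpr, tpr))
    tprs = np.asarray(tprs)
    return fpr_grid, tprs.mean(axis=0), tprs.std(axis=0)


def friedman_compare(metric_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test over a folds x feature-sets matrix.

    Within-fold average ranks with the standard tie correction; the p-value
    comes from the chi-square distribution with (sets - 1) degrees of
    freedom.  Degenerate matrices (all columns identical) return (0, 1).
    """
    m = np.asarray(metric_matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 folds and 2 feature sets")
    if np.allclose(m, m[:, [0]]):
        return 0.0, 1.0
    n, k = m.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    rsum = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * float(rsum @ rsum) - 3.0 * n * (k + 1)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    c = 1.0 - ties / (n * k * (k**2 - 1))
    if c <= 0:
        return 0.0, 1.0
    chi2 /= c
    p = float(stats.chi2.sf(chi2, k - 1))
    return float(chi2), p


def wilcoxon_pairwise(metric_matrix: np.ndarray) -> np.ndarray:
    """Symmetric matrix of exact two-sided Wilcoxon signed-rank p-values
    over feature-set pairs (unit diagonal; identical pairs give p=1)."""
    m = np.asarray(metric_matrix, dtype=float)
    k = m.shape[1]
    pmat = np.ones((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            diff = m[:, a] - m[:, b]
            if np.all(diff == 0):
                p = 1.0
            else:
                p = float(
                    stats.wilcoxon(m[:, a], m[:, b], method="exact").pvalue
                )
            pmat[a, b] = pmat[b, a] = p
    return pmat


@dataclass(frozen=True)
class ComparisonReport:
    """Per-feature-set summaries plus the Friedman / Wilcoxon statistics."""

    feature_sets: tuple[str, ...]
    summaries: dict[str, pd.DataFrame]  # feature set -> mean/sd per metric
    friedman: dict[str, tuple[float, float]]  # metric -> (chi2, p)
    wilcoxon: dict[str, np.ndarray] = field(default_factory=dict)  # metric -> p matrix


def compare_feature_sets(results: dict[str, CVResult]) -> ComparisonReport:
    """Build the feature-set comparison report from matched-fold CV runs."""
    names = tuple(results)
    metrics_names = ("accuracy", "f1", "auc")
    summaries = {name: cv.summary() for name, cv in results.items()}
    friedman, wilcox = {}, {}
    for metric in metrics_names:
        mat = np.column_stack([results[n].metric_matrix()[metric] for n in names])
        friedman[metric] = friedman_compare(mat)
        wilcox[metric] = wilcoxon_pairwise(mat)
    return ComparisonReport(names, summaries, friedman, wilcox)
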