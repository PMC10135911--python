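"""Per-class accuracy, ROC/PR curves with bootstrap error bars, network comparison.

Curves are computed at a fixed ladder of score-quantile thresholds so they
are comparable across classifiers; per-threshold means and SDs come from
bootstrap resamples of the (label, score) rows (500 by default).  AUC is
the trapezoidal area under the mean ROC curve.  One-class SVM produces no
false-positive rate and is evaluated by class-1 accuracy only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_grn import GoldStandard

logger = logging.getLogger(__name__)


class EvaluationError(ValueError):
    """Invalid evaluation input."""


# ---------------------------------------------------------------------------
# Point metrics
# ---------------------------------------------------------------------------

def class_accuracies(
    labels: np.ndarray, predictions: np.ndarray
) -> tuple[float, float]:
    """Per-class accuracies as percentages: (acc0, acc1)."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise EvaluationError("labels and predictions differ in length")
    accs = []
    for cls in (0, 1):
        mask = labels == cls
        if not np.any(mask):
            raise EvaluationError(f"class {cls} absent from labels")
        accs.append(100.0 * float(np.mean(predictions[mask] == cls)))
    return accs[0], accs[1]


def recall_precision(
    labels: np.ndarray, predictions: np.ndarray
) -> tuple[float, float]:
    """(recall %, precision %); precision is NaN when nothing is predicted positive."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    recall = 100.0 * tp / (tp + fn) if (tp + fn) else 0.0
    precision = 100.0 * tp / (tp + fp) if (tp + fp) else float("nan")
    return recall, precision


# ---------------------------------------------------------------------------
# Curves with bootstrap error bars
# ---------------------------------------------------------------------------

@dataclass
class CurveWithError:
    """A threshold-swept curve with per-threshold bootstrap means and SDs."""

    thresholds: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray
    y_sd: np.ndarray
    n_resamples: int = 500

    def __post_init__(self) -> None:
        n = len(self.thresholds)
        for arr in (self.x_mean, self.x_sd, self.y_mean, self.y_sd):
            if len(arr) != n:
                raise EvaluationError("curve vectors differ in length")

    def to_frame(self, x_name: str = "x", y_name: str = "y") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                f"{x_name}_mean": self.x_mean,
                f"{x_name}_sd": self.x_sd,
                f"{y_name}_mean": self.y_mean,
                f"{y_name}_sd": self.y_sd,
            }
        )


def _threshold_ladder(scores: np.ndarray, n_thresholds: int) -> np.ndarray:
    """Evenly spaced score quantiles, plus a sentinel above the maximum.

    The sentinel threshold classifies everything negative, anchoring the
    ROC curve at (0, 0); the minimum quantile classifies everything
    positive, anchoring (1, 1).
    """
    qs = np.linspace(0.0, 1.0, n_thresholds)
    ladder = np.quantile(scores, qs)
    sentinel = ladder[-1] + max(1.0, abs(ladder[-1]))
    return np.unique(np.append(ladder, sentinel))


def _validate_scores(labels: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores differ in length")
    if len(np.unique(labels)) < 2:
        raise EvaluationError("both classes must be present")
    return labels, scores


def _rates_at_thresholds(
    labels: np.ndarray, scores: np.ndarray, thresholds: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(TPR, FPR, precision) at every threshold; precision NaN where undefined."""
    # predicted positive iff score >= threshold
    pred = scores[None, :] >= thresholds[:, None]
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    tp = pred[:, pos].sum(axis=1)
    fp = pred[:, ~pos].sum(axis=1)
    tpr = tp / n_pos
    fpr = fp / n_neg
    denom = tp + fp
    with np.errstate(invalid="ignore"):
        precision = np.where(denom > 0, tp / np.maximum(denom, 1), np.nan)
    return tpr, fpr, precision


def _bootstrap_curves(
    labels: np.ndarray,
    scores: np.ndarray,
    thresholds: np.ndarray,
    n_resamples: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stacked (TPR, FPR, precision) arrays of shape (n_resamples, n_thresholds)."""
    rng = np.random.default_rng(seed)
    n = len(labels)
    tprs, fprs, precs = [], [], []
    draws = 0
    while len(tprs) < n_resamples:
        draws += 1
        if draws > n_resamples * 20:
            raise EvaluationError("could not draw class-complete resamples")
        idx = rng.integers(0, n, size=n)
        lab = labels[idx]
        if len(np.unique(lab)) < 2:
            continue
        tpr, fpr, prec = _rates_at_thresholds(lab, scores[idx], thresholds)
        tprs.append(tpr)
        fprs.append(fpr)
        precs.append(prec)
    return np.array(tprs), np.array(fprs), np.array(precs)


def auc_trapezoid(fpr: np.ndarray, tpr: np.ndarray) -> float:
    """Trapezoidal area under a (FPR, TPR) curve after monotone sorting."""
    order = np.lexsort((tpr, fpr))
    return float(np.trapezoid(tpr[order], fpr[order]))


def roc_with_error(
    labels: np.ndarray,
    scores: np.ndarray,
    n_thresholds: int = 101,
    n_resamples: int = 500,
    seed: int = 0,
) -> tuple[CurveWithError, float]:
    """ROC curve with bootstrap error bars and its AUC.

    Thresholds are evenly spaced score quantiles; each bootstrap resample
    of the (label, score) rows contributes a TPR/FPR at every threshold,
    summarized by mean ± SD.  AUC is the trapezoidal area under the mean
    curve sorted by FPR.
    """
    labels, scores = _validate_scores(labels, scores)
    thresholds = _threshold_ladder(scores, n_thresholds)
    tprs, fprs, _ = _bootstrap_curves(labels, scores, thresholds, n_resamples, seed)
    curve = CurveWithError(
        thresholds=thresholds,
        x_mean=fprs.mean(axis=0),
        x_sd=fprs.std(axis=0),
        y_mean=tprs.mean(axis=0),
        y_sd=tprs.std(axis=0),
        n_resamples=n_resamples,
    )
    return curve, auc_trapezoid(curve.x_mean, curve.y_mean)


def pr_with_error(
    labels: np.ndarray,
    scores: np.ndarray,
    n_thresholds: int = 101,
    n_resamples: int = 500,
    seed: int = 0,
) -> CurveWithError:
    """Precision–recall curve with bootstrap error bars (x=recall, y=precision).

    Thresholds where no resample predicts anything positive have undefined
    precision and are reported as NaN.
    """
    labels, scores = _validate_scores(labels, scores)
    thresholds = _threshold_ladder(scores, n_thresholds)
    tprs, _, precs = _bootstrap_curves(labels, scores, thresholds, n_resamples, seed)
    # the sentinel threshold predicts nothing positive: precision is NaN there
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return CurveWithError(
            thresholds=thresholds,
            x_mean=tprs.mean(axis=0),
            x_sd=tprs.std(axis=0),
            y_mean=np.nanmean(precs, axis=0),
            y_sd=np.nanstd(precs, axis=0),
            n_resamples=n_resamples,
        )


@dataclass
class EvaluationReport:
    """Summary metrics for one classifier on one dataset/benchmark."""

    class_accuracy_0: float | None
    class_accuracy_1: float
    recall: float
    precision: float
    auc: float | None
    roc: CurveWithError | None
    pr: CurveWithError | None
    dataset_tag: str = ""
    benchmark_tag: str = ""
    classifier_tag: str = ""

    def summary(self) -> dict:
        return {
            "dataset": self.dataset_tag,
            "benchmark": self.benchmark_tag,
            "classifier": self.classifier_tag,
            "class_accuracy_0": self.class_accuracy_0,
            "class_accuracy_1": self.class_accuracy_1,
            "recall": self.recall,
            "precision": self.precision,
            "auc": self.auc,
        }


def evaluate_classifier(
    labels: np.ndarray,
    scores: np.ndarray,
    predictions: np.ndarray,
    n_thresholds: int = 101,
    n_resamples: int = 500,
    seed: int = 0,
    one_class: bool = False,
    **tags: str,
) -> EvaluationReport:
    """Assemble a full report; one-class models skip ROC/PR and class-0 accuracy."""
    labels = np.asarray(labels, dtype=int)
    if one_class:
        mask = labels == 1
        if not np.any(mask):
            raise EvaluationError("no positive rows to evaluate")
        acc1 = 100.0 * float(np.mean(np.asarray(predictions)[mask] == 1))
        rec, prec = recall_precision(labels, predictions)
        return EvaluationReport(
            class_accuracy_0=None,
            class_accuracy_1=acc1,
            recall=rec,
            precision=prec,
            auc=None,
            roc=None,
            pr=None,
            dataset_tag=tags.get("dataset_tag", ""),
            benchmark_tag=tags.get("benchmark_tag", ""),
            classifier_tag=tags.get("classifier_tag", ""),
        )
    acc0, acc1 = class_accuracies(labels, predictions)
    rec, prec = recall_precision(labels, predictions)
    roc, auc = roc_with_error(labels, scores, n_thresholds, n_resamples, seed)
    pr = pr_with_error(labels, scores, n_thresholds, n_resamples, seed)
    return EvaluationReport(
        class_accuracy_0=acc0,
        class_accuracy_1=acc1,
        recall=rec,
        precision=prec,
        auc=auc,
        roc=roc,
        pr=pr,
        dataset_tag=tags.get("dataset_tag", ""),
        benchmark_tag=tags.get("benchmark_tag", ""),
        classifier_tag=tags.get("classifier_tag", ""),
    )


# ---------------------------------------------------------------------------
# Network comparison (per-TF edge categories)
# ---------------------------------------------------------------------------

@dataclass
class PredictionComparison:
    """Per-TF partition of two predicted edge sets against a gold standard.

    ``shared_validated`` = A ∩ B ∩ gold; ``shared_unvalidated`` = (A ∩ B) \\ gold;
    ``unique_a`` = A \\ B; ``unique_b`` = B \\ A.  Categories are pairwise
    disjoint and their union is A ∪ B.
    """

    tf: str
    shared_validated: set[tuple[str, str]]
    shared_unvalidated: set[tuple[str, str]]
    unique_a: set[tuple[str, str]]
    unique_b: set[tuple[str, str]]

    CATEGORIES = ("shared_validated", "shared_unvalidated", "unique_a", "unique_b")

    def all_edges(self) -> set[tuple[str, str]]:
        return (
            self.shared_validated
            | self.shared_unvalidated
            | self.unique_a
            | self.unique_b
        )

    def category_of(self) -> dict[tuple[str, str], str]:
        out = {}
        for name in self.CATEGORIES:
            for edge in getattr(self, name):
                out[edge] = name
        return out


def compare_networks(
    pred_a: set[tuple[str, str]],
    pred_b: set[tuple[str, str]],
    gold: GoldStandard,
    tf: str,
) -> PredictionComparison:
    """Categorize two methods' predicted edges for one TF against the gold set."""
    a = {e for e in pred_a if e[0] == tf}
    b = {e for e in pred_b if e[0] == tf}
    g = {e for e in gold.edges if e[0] == tf}
    shared = a & b
    return PredictionComparison(
        tf=tf,
        shared_validated=shared & g,
        shared_unvalidated=shared - g,
        unique_a=a - b,
        unique_b=b - a,
    )


def export_network(
    comparison: PredictionComparison,
    path: str | Path,
    format: str = "TSV",
) -> None:
    """Write the categorized edges as SIF ("TF <category> target") or TSV."""
    fmt = format.upper()
    categories = comparison.category_of()
    rows = sorted(categories.items())
    if fmt == "SIF":
        with open(path, "w") as fh:
            for (tf, target), cat in rows:
                fh.write(f"{tf}\t{cat}\t{target}\n")
    elif fmt == "TSV":
        frame = pd.DataFrame(
            [(tf, target, cat) for (tf, target), cat in rows],
            columns=["regulator", "target", "category"],
        )
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise EvaluationError(f"unknown export format {format!r}")


def read_network(path: str | Path, format: str = "TSV") -> PredictionComparison | pd.DataFrame:
    """Round-trip reader for exported comparisons (TSV form)."""
    fmt = format.upper()
    if fmt == "TSV":
        return pd.read_csv(path, sep="\t")
    if fmt == "SIF":
        return pd.read_csv(
            path, sep="\t", names=["regulator", "category", "target"]
        )
    raise EvaluationError(f"unknown format {format!r}")
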