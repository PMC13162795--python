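"""Performance metrics, statistical comparison suite, calibration, ablation.

Threshold metrics follow the standard confusion-count formulas; ranking
metrics (ROC AUC, step-integrated PR AUC) go through scikit-learn. Model
comparison implements Dietterich's 5x2cv paired t-test and McNemar's test
(continuity-corrected chi-square, exact binomial for sparse discordants),
with Bonferroni adjustment and seeded percentile-bootstrap confidence
intervals. Calibration reports reliability bins, expected calibration
error (ECE) on the maximum fuzzy membership, and the distribution of
predictions across the clinical confidence bands. The leave-one-metric-out
ablation redistributes the dropped distance weight proportionally and
re-runs the fusion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .fusion import (
    CONFIDENCE_LEVELS,
    ConfidenceMatrix,
    DistanceWeights,
    FusionResult,
    fuse,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "CalibrationReport",
    "classification_metrics",
    "ranking_metrics",
    "five_by_two_cv_ttest",
    "mcnemar",
    "mcnemar_statistic",
    "bonferroni",
    "bootstrap_ci",
    "calibration_report",
    "ablation",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, y_pred, y_true) -> "ConfusionCounts":
        y_pred = np.asarray(y_pred).astype(int)
        y_true = np.asarray(y_true).astype(int)
        return cls(
            TP=int(np.sum((y_pred == 1) & (y_true == 1))),
            TN=int(np.sum((y_pred == 0) & (y_true == 0))),
            FP=int(np.sum((y_pred == 1) & (y_true == 0))),
            FN=int(np.sum((y_pred == 0) & (y_true == 1))),
        )


@dataclass
class MetricReport:
    """Threshold and (optionally) ranking metrics; NaN marks an undefined
    metric (e.g. precision with no positive predictions)."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None
    pr_auc: float | None = None
    n: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "pr_auc": self.pr_auc,
            "n": self.n,
        }


def classification_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    An undefined ratio (zero denominator) is reported as NaN with a log
    message rather than silently coerced to 0.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    acc = (counts.TP + counts.TN) / counts.total
    if counts.TP + counts.FP == 0:
        logger.warning("precision undefined: no positive predictions")
        prec = math.nan
    else:
        prec = counts.TP / (counts.TP + counts.FP)
    if counts.TP + counts.FN == 0:
        logger.warning("recall undefined: no positive labels")
        rec = math.nan
    else:
        rec = counts.TP / (counts.TP + counts.FN)
    denom = 2 * counts.TP + counts.FP + counts.FN
    f1 = 2 * counts.TP / denom if denom else math.nan
    return MetricReport(accuracy=acc, precision=prec, recall=rec, f1=f1, n=counts.total)


def ranking_metrics(scores, labels) -> tuple[float, float]:
    """ROC AUC (Mann-Whitney, ties averaged) and step-integrated PR AUC."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ranking metrics need both classes present")
    return float(roc_auc_score(labels, scores)), float(average_precision_score(labels, scores))


@dataclass
class FiveByTwoResult:
    t: float
    p: float
    degenerate_variance: bool = False
    differences: np.ndarray | None = None


def five_by_two_cv_ttest(X, y, builder_a, builder_b, seed: int = 0) -> FiveByTwoResult:
    """Dietterich's 5x2cv paired t-test on accuracy.

    ``builder_a`` / ``builder_b`` are zero-argument callables returning
    unfitted classifiers. Five replications of stratified 2-fold CV give
    ten accuracy differences; the statistic is the first-replication
    difference over the root mean of the per-replication variances, with
    5 degrees of freedom. Identical performance across all folds yields a
    degenerate-variance flag and p = 1.
    """
    y = np.asarray(y).astype(int)
    diffs = np.empty((5, 2))
    for r in range(5):
        cv = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed + r)
        for k, (train, test) in enumerate(cv.split(np.zeros(len(y)), y)):
            Xtr = X.iloc[train] if hasattr(X, "iloc") else X[train]
            Xte = X.iloc[test] if hasattr(X, "iloc") else X[test]
            acc = []
            for builder in (builder_a, builder_b):
                model = builder().fit(Xtr, y[train])
                acc.append(np.mean(model.predict(Xte) == y[test]))
            diffs[r, k] = acc[0] - acc[1]
    means = diffs.mean(axis=1)
    s2 = ((diffs[:, 0] - means) ** 2 + (diffs[:, 1] - means) ** 2)
    denom = math.sqrt(s2.mean())
    if denom == 0:
        return FiveByTwoResult(t=0.0, p=1.0, degenerate_variance=True, differences=diffs)
    t = diffs[0, 0] / denom
    p = 2 * stats.t.sf(abs(t), df=5)
    return FiveByTwoResult(t=float(t), p=float(p), differences=diffs)


@dataclass
class McNemarResult:
    statistic: float
    p: float
    b: int
    c: int
    exact: bool = False
    degenerate: bool = False


def mcnemar_statistic(b: int, c: int) -> float:
    """Continuity-corrected McNemar statistic ``(|b-c|-1)^2 / (b+c)``.

    The correction is floored at 0 so equal discordant counts give 0.
    """
    if b + c == 0:
        raise ValueError("no discordant pairs")
    return max(abs(b - c) - 1.0, 0.0) ** 2 / (b + c)


def mcnemar(preds_a, preds_b, labels) -> McNemarResult:
    """McNemar's test on paired predictions.

    The continuity-corrected statistic is always reported; its p-value is
    chi-square(1) except with fewer than 25 discordant pairs, where the
    exact binomial test is used. No discordant pairs at all gives p = 1
    with a flag.
    """
    preds_a = np.asarray(preds_a).astype(int)
    preds_b = np.asarray(preds_b).astype(int)
    labels = np.asarray(labels).astype(int)
    if not (len(preds_a) == len(preds_b) == len(labels)):
        raise ValueError("prediction and label vectors must have equal length")
    a_right = preds_a == labels
    b_right = preds_b == labels
    b = int(np.sum(a_right & ~b_right))
    c = int(np.sum(~a_right & b_right))
    if b + c == 0:
        return McNemarResult(statistic=0.0, p=1.0, b=b, c=c, degenerate=True)
    stat = mcnemar_statistic(b, c)
    if b + c < 25:
        p = stats.binomtest(b, b + c, 0.5).pvalue
        return McNemarResult(statistic=float(stat), p=float(p), b=b, c=c, exact=True)
    p = stats.chi2.sf(stat, df=1)
    return McNemarResult(statistic=float(stat), p=float(p), b=b, c=c)


def bonferroni(alpha: float, k: int) -> float:
    """Family-wise adjusted significance threshold alpha / k."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha!r}")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k!r}")
    return alpha / k


def bootstrap_ci(
    metric_fn,
    scores,
    labels,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    needs_both_classes: bool = False,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for ``metric_fn(scores, labels)``.

    A resample collapsing to a single class is redrawn (up to 100 times)
    when the metric needs both classes.
    """
    scores = np.asarray(scores)
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two samples to bootstrap")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for i in range(B):
        for _attempt in range(101):
            idx = rng.integers(0, n, size=n)
            if not needs_both_classes or len(np.unique(labels[idx])) == 2:
                break
        else:  # pragma: no cover - requires pathological inputs
            raise RuntimeError("could not draw a two-class resample in 100 retries")
        vals[i] = metric_fn(scores[idx], labels[idx])
    lo, hi = np.percentile(vals, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


@dataclass
class CalibrationReport:
    bin_edges: np.ndarray
    bin_confidence: np.ndarray
    bin_accuracy: np.ndarray
    bin_weight: np.ndarray
    ece: float
    level_distribution: dict
    axis: str = "mu_max"
    n_bins: int = 10


def calibration_report(
    results: list[FusionResult], labels, n_bins: int = 10, axis: str = "mu_max"
) -> CalibrationReport:
    """Reliability bins, ECE and the confidence-band distribution.

    Predicted confidence defaults to the maximum fuzzy membership (the
    quantity the triage thresholds act on); ``axis='fuzzy_score'``
    switches to the normalised score. Confidence values are binned into
    ``n_bins`` equal-width bins over (0, 1]; empty bins carry weight 0 and
    are excluded from the ECE sum.
    """
    if len(results) == 0:
        raise ValueError("no fusion results to calibrate")
    labels = np.asarray(labels).astype(int)
    if axis == "mu_max":
        conf = np.array([r.mu_max for r in results])
    elif axis == "fuzzy_score":
        conf = np.array([max(r.fuzzy_score, 1 - r.fuzzy_score) for r in results])
    else:
        raise ValueError(f"unknown calibration axis {axis!r}")
    correct = np.array([r.label for r in results]) == labels

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # bin b covers (edges[b], edges[b+1]]; conf values are in (0, 1]
    bin_idx = np.clip(np.ceil(conf * n_bins).astype(int) - 1, 0, n_bins - 1)
    bin_conf = np.full(n_bins, np.nan)
    bin_acc = np.full(n_bins, np.nan)
    weight = np.zeros(n_bins)
    for b in range(n_bins):
        mask = bin_idx == b
        if mask.any():
            weight[b] = mask.mean()
            bin_conf[b] = conf[mask].mean()
            bin_acc[b] = correct[mask].mean()
    occupied = weight > 0
    ece = float(np.sum(weight[occupied] * np.abs(bin_acc[occupied] - bin_conf[occupied])))

    levels = [r.confidence_level for r in results]
    dist = {lvl: levels.count(lvl) / len(levels) for lvl in CONFIDENCE_LEVELS}
    return CalibrationReport(
        bin_edges=edges, bin_confidence=bin_conf, bin_accuracy=bin_acc,
        bin_weight=weight, ece=ece, level_distribution=dist, axis=axis, n_bins=n_bins,
    )


@dataclass
class AblationResult:
    dropped: str
    weights: DistanceWeights
    report: MetricReport
    full_report: MetricReport

    @property
    def delta_accuracy(self) -> float:
        return self.report.accuracy - self.full_report.accuracy


def ablation(
    matrix: ConfidenceMatrix,
    labels,
    weights: DistanceWeights,
    beta: float,
    metric_to_drop: str,
    normalize: bool = True,
) -> AblationResult:
    """Leave-one-distance-out ablation of the fusion.

    The dropped metric's weight is redistributed proportionally among the
    remaining three and the fused decision is re-evaluated; the report
    carries the full-configuration metrics alongside for the delta.
    """
    labels = np.asarray(labels).astype(int)

    def evaluate(w: DistanceWeights) -> MetricReport:
        results = fuse(matrix, weights=w, beta=beta, normalize=normalize)
        preds = np.array([r.label for r in results])
        scores = np.array([r.fuzzy_score for r in results])
        rep = classification_metrics(ConfusionCounts.from_predictions(preds, labels))
        if len(np.unique(labels)) == 2:
            rep.auc, rep.pr_auc = ranking_metrics(scores, labels)
        return rep

    reduced = weights.drop(metric_to_drop)
    return AblationResult(
        dropped=metric_to_drop,
        weights=reduced,
        report=evaluate(reduced),
        full_report=evaluate(weights),
    )
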