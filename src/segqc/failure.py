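"""Segmentation failure detection from aggregated uncertainty.

Subject-level uncertainty aggregates are scored against the true
segmentation quality (Dice coefficient).  Quality is binarized into
successful/failed at a per-region Dice cutoff (taken from inter-rater
agreement levels; there is no hidden default — the cutoff is a required
configuration value).  Failure is the positive class throughout; aggregation
scores are oriented so that *lower* score means *more likely failed*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .datamodel import _as_bool


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|P∩G| / (|P|+|G|); both empty → 1, one empty → 0."""
    pred = _as_bool(pred, "pred")
    gt = _as_bool(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    np_, ng = int(pred.sum()), int(gt.sum())
    if np_ + ng == 0:
        return 1.0
    return 2.0 * int((pred & gt).sum()) / (np_ + ng)


def binarize_quality(dice_values, cutoff: float) -> np.ndarray:
    """Failure labels: dice < cutoff → failed (1, positive class).

    A Dice exactly at the cutoff counts as successful.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must lie in (0, 1), got {cutoff}")
    d = np.asarray(dice_values, dtype=float)
    return (d < cutoff).astype(int)


def spearman_correlation(predicted, actual) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined) for constant inputs.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(actual, dtype=float)
    if x.size != y.size:
        raise ValueError("predicted and actual lengths differ")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


def roc_from_scores(scores, failure_labels):
    """ROC of the failure-detection problem.

    ``scores`` are predicted-quality scores (higher = predicted better);
    the ROC ranks subjects by −score so that low predicted quality flags
    failure.  Returns (fpr, tpr, thresholds, auc); all NaN when only one
    class is present (undefined, reported as missing).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(failure_labels, dtype=int)
    if s.size != y.size:
        raise ValueError("scores and labels lengths differ")
    if len(np.unique(y)) < 2:
        nan = np.array([np.nan])
        return nan, nan, nan, float("nan")
    fpr, tpr, thr = roc_curve(y, -s)
    # AUC via the probabilistic definition: P(score_failed < score_success)
    # plus half the tie probability.
    failed, success = s[y == 1], s[y == 0]
    less = (failed[:, None] < success[None, :]).mean()
    ties = (failed[:, None] == success[None, :]).mean()
    return fpr, tpr, thr, float(less + 0.5 * ties)


def youden_accuracy(fpr, tpr, thresholds, scores, failure_labels):
    """Operating point maximizing Youden's J = sensitivity − (1 − specificity).

    Ties in J are broken toward higher specificity (lower FPR).  Accuracy is
    evaluated on the same cohort at the chosen threshold (apparent
    accuracy): a subject is flagged failed when −score ≥ threshold.
    """
    fpr = np.asarray(fpr, dtype=float)
    tpr = np.asarray(tpr, dtype=float)
    j = tpr - fpr
    # roc_curve orders by increasing fpr, so argmax lands on the lowest fpr
    # among ties.
    best = int(np.argmax(j))
    thr = float(thresholds[best])
    s = np.asarray(scores, dtype=float)
    y = np.asarray(failure_labels, dtype=int)
    predicted_failed = (-s >= thr).astype(int)
    accuracy = float((predicted_failed == y).mean())
    return thr, accuracy


@dataclass
class FailureDetectionResult:
    """Predicted-vs-true quality pairs and their summary metrics for a region."""

    region: str
    predicted_scores: np.ndarray
    true_dice: np.ndarray
    failure_labels: np.ndarray
    dice_cutoff: float
    spearman_rho: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc_roc: float
    youden_threshold: float
    youden_accuracy: float

    def summary(self) -> dict[str, float]:
        return {
            "region": self.region,
            "n_subjects": int(len(self.true_dice)),
            "n_failed": int(self.failure_labels.sum()),
            "dice_cutoff": self.dice_cutoff,
            "spearman_rho": self.spearman_rho,
            "auc_roc": self.auc_roc,
            "youden_threshold": self.youden_threshold,
            "youden_accuracy": self.youden_accuracy,
        }


def evaluate_failure_detection(
    predicted_scores,
    true_dice,
    cutoff: float,
    region: str = "WT",
) -> FailureDetectionResult:
    """Full subject-level evaluation of one aggregation method.

    ``predicted_scores`` may be predicted Dice values or any monotone
    quality score (e.g. negative mean uncertainty); higher must mean
    predicted better.
    """
    s = np.asarray(predicted_scores, dtype=float)
    d = np.asarray(true_dice, dtype=float)
    if s.size != d.size:
        raise ValueError("scores and dice lengths differ")
    if s.size < 2:
        raise ValueError("need at least 2 subjects")
    labels = binarize_quality(d, cutoff)
    rho = spearman_correlation(s, d) if s.size >= 3 else float("nan")
    fpr, tpr, thr, auc = roc_from_scores(s, labels)
    if np.isnan(auc):
        yt, ya = float("nan"), float("nan")
    else:
        yt, ya = youden_accuracy(fpr, tpr, thr, s, labels)
    return FailureDetectionResult(
        region=region,
        predicted_scores=s,
        true_dice=d,
        failure_labels=labels,
        dice_cutoff=float(cutoff),
        spearman_rho=rho,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        auc_roc=auc,
        youden_threshold=yt,
        youden_accuracy=ya,
    )
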