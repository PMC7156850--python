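"""Segmentation error maps and uncertainty-error localization statistics.

A model that knows where it errs should be uncertain exactly on its
misclassified voxels.  The uncertainty-error overlap (U-E) quantifies this as
the Dice overlap between the thresholded-uncertainty region U = {q ≥ t} and
the error region E = FP ∪ FN; being restricted to U ∪ E it ignores the
(typically huge) confidently-correct background.  The operating threshold t
is chosen per uncertainty method by sweeping t ∈ {0.05, 0.10, …, 0.95} and
maximizing mean subject U-E on the validation split; the frozen threshold is
then applied to test subjects and reused by feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import average_precision_score

from .datamodel import SubjectRecord, UncertaintyMap, _as_bool
from .uncertainty import normalized_entropy

#: The 19 candidate thresholds 0.05 … 0.95 in steps of 0.05.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(1, 20) * 0.05, 2).tolist()
)


@dataclass
class ErrorMap:
    """Binary map of misclassified voxels (union of FP and FN)."""

    values: np.ndarray
    region: str = "WT"

    def __post_init__(self) -> None:
        self.values = _as_bool(self.values, "error map")


def error_map(pred: np.ndarray, gt: np.ndarray, region: str = "WT") -> ErrorMap:
    """E = pred XOR gt: false positives united with false negatives."""
    pred = _as_bool(pred, "pred")
    gt = _as_bool(gt, "gt")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
    return ErrorMap(pred ^ gt, region=region)


def uncertainty_error_overlap(
    q: UncertaintyMap,
    e: ErrorMap,
    threshold: float,
    mask: np.ndarray | None = None,
) -> float:
    """Dice overlap between U = {q ≥ threshold} and the error region E.

    Conventions: 1.0 when both U and E are empty (a perfect segmentation
    with no thresholded uncertainty is perfect localization), 0.0 when
    exactly one is empty.  The threshold is closed (q ≥ t) so the top grid
    value 0.95 is attainable at q = 0.95.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    u = q.values >= threshold
    ev = e.values
    if u.shape != ev.shape:
        raise ValueError(f"shape mismatch: q {u.shape} vs E {ev.shape}")
    if mask is not None:
        m = _as_bool(mask, "mask")
        u, ev = u & m, ev & m
    nu, ne = int(u.sum()), int(ev.sum())
    if nu + ne == 0:
        return 1.0
    return 2.0 * int((u & ev).sum()) / (nu + ne)


@dataclass
class ThresholdSelection:
    """Uncertainty threshold frozen from a validation-split sweep."""

    method_id: str
    region: str
    threshold: float
    sweep_scores: dict[float, float]

    def __post_init__(self) -> None:
        best = max(self.sweep_scores.values())
        if self.sweep_scores[self.threshold] < best - 1e-12:
            raise ValueError("selected threshold does not attain the sweep maximum")


def select_threshold_from_maps(
    pairs: Sequence[tuple[UncertaintyMap, ErrorMap]],
    method_id: str = "method",
    region: str = "WT",
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    masks: Sequence[np.ndarray] | None = None,
) -> ThresholdSelection:
    """Sweep the threshold grid; score = mean subject U-E; ties → lower t."""
    if not pairs:
        raise ValueError("empty validation set for threshold selection")
    if masks is None:
        masks = [None] * len(pairs)
    sweep: dict[float, float] = {}
    for t in grid:
        scores = [
            uncertainty_error_overlap(q, e, t, mask)
            for (q, e), mask in zip(pairs, masks, strict=True)
        ]
        sweep[float(t)] = float(np.mean(scores))
    thresholds = sorted(sweep)  # ascending, so argmax picks the lowest tie
    best = thresholds[int(np.argmax([sweep[t] for t in thresholds]))]
    return ThresholdSelection(
        method_id=method_id, region=region, threshold=best, sweep_scores=sweep
    )


def subject_uncertainty(record: SubjectRecord, region: str) -> UncertaintyMap:
    """Uncertainty map for a subject: native if present, else entropy of prob."""
    if record.uncertainty_maps and region in record.uncertainty_maps:
        return record.uncertainty_maps[region]
    if record.prob_maps and region in record.prob_maps:
        return normalized_entropy(record.prob_maps[region], region=region)
    raise ValueError(
        f"subject {record.subject_id} has neither uncertainty nor prob map for {region}"
    )


def select_threshold(
    method_id: str,
    validation_subjects: Sequence[SubjectRecord],
    region: str,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> ThresholdSelection:
    """Protocol wrapper: build (q, E) pairs from validation subjects and sweep."""
    pairs = [
        (
            subject_uncertainty(rec, region),
            error_map(rec.pred_labels[region], rec.gt_labels[region], region),
        )
        for rec in validation_subjects
    ]
    masks = [rec.brain_mask for rec in validation_subjects]
    return select_threshold_from_maps(
        pairs, method_id=method_id, region=region, grid=grid, masks=masks
    )


def uncertainty_error_auc_pr(
    q: UncertaintyMap, e: ErrorMap, mask: np.ndarray | None = None
) -> float:
    """Threshold-free precision-recall AUC of q as a misclassification score.

    Returns NaN when E has no positive voxel inside the mask (undefined,
    reported as missing).  Invariant under strictly increasing transforms
    of q.
    """
    scores = q.values
    labels = e.values
    if mask is not None:
        m = _as_bool(mask, "mask")
        scores, labels = scores[m], labels[m]
    else:
        scores, labels = scores.ravel(), labels.ravel()
    if not labels.any():
        return float("nan")
    return float(average_precision_score(labels.astype(int), scores))
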