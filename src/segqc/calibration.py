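"""Reliability diagrams and calibration errors at dataset and subject level.

A model is calibrated when voxels predicted foreground with probability p are
foreground with empirical frequency p.  The confidence axis is the foreground
probability (calibration-curve style): per bin m, c_m is the mean predicted
foreground probability and a_m the empirical foreground fraction.  Dataset
scope pools the voxels of all subjects into one diagram; subject scope uses a
single subject's voxels, which is the clinically relevant level — good pooled
calibration can mask opposing subject-level miscalibrations that average out.

All voxel-level quantities are restricted to an evaluation mask (typically
the skull-stripped brain) to avoid inflation by trivially correct background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import SubjectRecord
from .uncertainty import _check_unit_interval, uncertainty_to_confidence

DEFAULT_N_BINS = 10
#: Signed-error tolerance below which a subject counts as well calibrated.
DEFAULT_CLASS_TOLERANCE = 0.01


@dataclass
class ReliabilityDiagram:
    """Binned (confidence, accuracy, count) triples.

    Empty bins carry NaN confidence/accuracy and are flagged via
    ``occupied``; they contribute nothing to ECE and are excluded from ACE.
    """

    bin_edges: np.ndarray  # (M+1,) ascending, spanning [0, 1]
    confidences: np.ndarray  # c_m, NaN where empty
    accuracies: np.ndarray  # a_m, NaN where empty
    counts: np.ndarray  # n_m
    scope: str = "subject"
    region: str = "WT"

    def __post_init__(self) -> None:
        if self.scope not in ("dataset", "subject"):
            raise ValueError(f"scope must be 'dataset' or 'subject', got {self.scope!r}")
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.confidences = np.asarray(self.confidences, dtype=float)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def n_voxels(self) -> int:
        return int(self.counts.sum())

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lower": self.bin_edges[:-1],
                "bin_upper": self.bin_edges[1:],
                "confidence": self.confidences,
                "accuracy": self.accuracies,
                "count": self.counts,
            }
        )


def _collect(volumes, masks, name: str) -> np.ndarray:
    """Flatten one volume or a sequence of volumes restricted to masks."""
    if isinstance(volumes, np.ndarray):
        volumes = [volumes]
        masks = [masks]
    elif masks is None:
        masks = [None] * len(volumes)
    parts = []
    for v, m in zip(volumes, masks, strict=True):
        v = np.asarray(v)
        parts.append(v.ravel() if m is None else v[np.asarray(m, dtype=bool)])
    return np.concatenate(parts) if parts else np.array([])


def reliability_diagram(
    conf,
    gt,
    mask=None,
    n_bins: int = DEFAULT_N_BINS,
    scope: str = "subject",
    region: str = "WT",
) -> ReliabilityDiagram:
    """Bin masked voxels by predicted foreground probability.

    ``conf``/``gt``/``mask`` are either single volumes (subject scope) or
    sequences of volumes whose voxels are pooled (dataset scope).  Bins are
    equal-width on [0, 1], with the upper bin right-closed so conf = 1 lands
    in the top bin.
    """
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    c = _collect(conf, mask, "conf")
    g = _collect(gt, mask, "gt")
    if c.size == 0:
        raise ValueError("empty evaluation mask: no voxels to bin")
    if c.shape != g.shape:
        raise ValueError("conf and gt select different numbers of voxels")
    c = _check_unit_interval(c, "conf")
    g = g.astype(float)

    idx = np.minimum((c * n_bins).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        conf_mean = np.bincount(idx, weights=c, minlength=n_bins) / counts
        acc_mean = np.bincount(idx, weights=g, minlength=n_bins) / counts
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    return ReliabilityDiagram(edges, conf_mean, acc_mean, counts, scope=scope, region=region)


def expected_calibration_error(diagram: ReliabilityDiagram) -> float:
    """ECE = Σ_m (n_m / N) |c_m − a_m|; empty bins contribute 0."""
    occ = diagram.occupied
    n = diagram.n_voxels
    if n == 0:
        raise ValueError("diagram has no voxels")
    w = diagram.counts[occ] / n
    return float(np.sum(w * np.abs(diagram.confidences[occ] - diagram.accuracies[occ])))


def average_calibration_error(diagram: ReliabilityDiagram) -> float:
    """Unweighted mean of |c_m − a_m| over occupied bins only."""
    occ = diagram.occupied
    if not occ.any():
        raise ValueError("diagram has no occupied bins")
    return float(
        np.mean(np.abs(diagram.confidences[occ] - diagram.accuracies[occ]))
    )


def signed_calibration_error(diagram: ReliabilityDiagram) -> float:
    """Count-weighted signed miscalibration, folded around confidence 0.5.

    On the foreground-probability axis the predicted class flips at 0.5:
    for bins at or above 0.5 the predicted-class confidence error is
    c_m − a_m, for bins below 0.5 it is (1−c_m) − (1−a_m) = a_m − c_m.
    Folding makes the sign track over-/underconfidence of the predicted
    class; the unfolded sum would cancel symmetric tail sharpening.
    """
    occ = diagram.occupied
    n = diagram.n_voxels
    if n == 0:
        raise ValueError("diagram has no voxels")
    centers = 0.5 * (diagram.bin_edges[:-1] + diagram.bin_edges[1:])
    sign = np.where(centers >= 0.5, 1.0, -1.0)
    w = diagram.counts[occ] / n
    dev = diagram.confidences[occ] - diagram.accuracies[occ]
    return float(np.sum(w * sign[occ] * dev))


def classify_subject_calibration(
    diagram: ReliabilityDiagram, tolerance: float = DEFAULT_CLASS_TOLERANCE
) -> str:
    """Classify a subject diagram as over-/underconfident or well calibrated.

    Uses the folded signed error S: S > tolerance → ``overconfident``
    (confidences sharper than empirical frequencies), S < −tolerance →
    ``underconfident``, otherwise ``well_calibrated``.
    """
    if diagram.scope != "subject":
        raise ValueError("calibration classification applies to subject-scope diagrams")
    s = signed_calibration_error(diagram)
    if s > tolerance:
        return "overconfident"
    if s < -tolerance:
        return "underconfident"
    return "well_calibrated"


def confidence_map(record: SubjectRecord, region: str) -> np.ndarray:
    """Foreground-probability surrogate for one subject and region.

    Probability-native methods supply the probability map directly;
    uncertainty-native methods are translated via y(1 − 0.5q) + (1 − y)0.5q
    using the predicted labels.
    """
    if record.prob_maps and region in record.prob_maps:
        return record.prob_maps[region]
    if record.uncertainty_maps and region in record.uncertainty_maps:
        return uncertainty_to_confidence(
            record.uncertainty_maps[region], record.pred_labels[region]
        )
    raise ValueError(
        f"subject {record.subject_id} has neither prob nor uncertainty map for {region}"
    )


def mean_subject_ece(
    subjects: Sequence[SubjectRecord],
    region: str,
    n_bins: int = DEFAULT_N_BINS,
    tolerance: float = DEFAULT_CLASS_TOLERANCE,
) -> tuple[float, pd.DataFrame]:
    """Per-subject ECE within the brain mask, then unweighted subject mean.

    Subjects with an empty brain mask are excluded with a warning and appear
    in the returned table with NaN metrics.
    """
    rows = []
    eces = []
    for rec in subjects:
        if not rec.brain_mask.any():
            warnings.warn(
                f"subject {rec.subject_id} has an empty brain mask; excluded",
                stacklevel=2,
            )
            rows.append(
                dict(subject_id=rec.subject_id, region=region, ece=np.nan,
                     ace=np.nan, calibration_class="excluded")
            )
            continue
        conf = confidence_map(rec, region)
        diagram = reliability_diagram(
            conf, rec.gt_labels[region], rec.brain_mask, n_bins=n_bins,
            scope="subject", region=region,
        )
        ece = expected_calibration_error(diagram)
        rows.append(
            dict(
                subject_id=rec.subject_id,
                region=region,
                ece=ece,
                ace=average_calibration_error(diagram),
                calibration_class=classify_subject_calibration(diagram, tolerance),
            )
        )
        eces.append(ece)
    if not eces:
        raise ValueError("no subject with a non-empty brain mask")
    return float(np.mean(eces)), pd.DataFrame(rows)


def dataset_ece(
    subjects: Sequence[SubjectRecord],
    region: str,
    n_bins: int = DEFAULT_N_BINS,
) -> float:
    """Pooled dataset-level ECE over all subjects' brain voxels."""
    confs = [confidence_map(r, region) for r in subjects]
    gts = [r.gt_labels[region] for r in subjects]
    masks = [r.brain_mask for r in subjects]
    diagram = reliability_diagram(
        confs, gts, masks, n_bins=n_bins, scope="dataset", region=region
    )
    return expected_calibration_error(diagram)
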