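"""End-to-end orchestration: voxel-level evaluation and failure detection.

``evaluate_voxel`` reproduces the voxel-level protocol — per-subject
reliability/ECE/ACE within the brain mask, pooled dataset-level calibration,
U-E threshold selection on the validation split, and U-E / PR-AUC on the
test split.  ``detect_failures`` runs the subject-level protocol — feature
extraction for the three aggregation families, random-forest Dice
regression fitted on the training split, and Spearman ρ / AUC-ROC / Youden
accuracy of failure detection on the test split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregation import (
    DiceRegressor,
    SubjectFeatures,
    features_frame,
    mean_aggregate,
    prior_knowledge_features,
)
from .calibration import (
    DEFAULT_CLASS_TOLERANCE,
    DEFAULT_N_BINS,
    ReliabilityDiagram,
    average_calibration_error,
    classify_subject_calibration,
    confidence_map,
    expected_calibration_error,
    reliability_diagram,
)
from .datamodel import Cohort, SubjectRecord
from .failure import FailureDetectionResult, dice_coefficient, evaluate_failure_detection
from .localization import (
    DEFAULT_THRESHOLD_GRID,
    ThresholdSelection,
    error_map,
    select_threshold,
    subject_uncertainty,
    uncertainty_error_auc_pr,
    uncertainty_error_overlap,
)
from .texture import automatic_features

AGGREGATION_FAMILIES = ("mean", "prior_knowledge", "automatic")


def _diagram_to_dict(d: ReliabilityDiagram) -> dict:
    return {
        "scope": d.scope,
        "region": d.region,
        "bin_edges": d.bin_edges.tolist(),
        "confidences": [None if np.isnan(c) else c for c in d.confidences],
        "accuracies": [None if np.isnan(a) else a for a in d.accuracies],
        "counts": d.counts.tolist(),
    }


@dataclass
class VoxelEvaluation:
    """Outputs of the voxel-level protocol."""

    subject_calibration: pd.DataFrame
    dataset_diagrams: dict[str, ReliabilityDiagram]
    dataset_ece: pd.DataFrame
    threshold_selections: dict[str, ThresholdSelection]
    test_localization: pd.DataFrame

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.subject_calibration.to_csv(out_dir / "subject_calibration.csv", index=False)
        self.dataset_ece.to_csv(out_dir / "dataset_ece.csv", index=False)
        self.test_localization.to_csv(out_dir / "test_localization.csv", index=False)
        diagrams = {r: _diagram_to_dict(d) for r, d in self.dataset_diagrams.items()}
        (out_dir / "dataset_reliability.json").write_text(json.dumps(diagrams, indent=1))
        sel = {
            r: {
                "method_id": s.method_id,
                "region": s.region,
                "threshold": s.threshold,
                "sweep": {f"{t:.2f}": v for t, v in sorted(s.sweep_scores.items())},
            }
            for r, s in self.threshold_selections.items()
        }
        (out_dir / "threshold_selection.json").write_text(json.dumps(sel, indent=1))


def evaluate_voxel(
    cohort: Cohort,
    n_bins: int = DEFAULT_N_BINS,
    tolerance: float = DEFAULT_CLASS_TOLERANCE,
    threshold_grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    method_id: str = "method",
    regions: Sequence[str] | None = None,
) -> VoxelEvaluation:
    """Voxel-level calibration and error-localization evaluation.

    Subjects lacking both probability and uncertainty maps are skipped with
    a warning row.  Threshold selection requires a non-empty validation
    split; localization metrics are reported on the test split.
    """
    regions = tuple(regions or cohort.region_set)
    rows = []
    for rec in cohort:
        for region in regions:
            try:
                conf = confidence_map(rec, region)
            except ValueError:
                rows.append(
                    dict(subject_id=rec.subject_id, split=rec.split, region=region,
                         ece=np.nan, ace=np.nan, calibration_class="skipped")
                )
                continue
            diagram = reliability_diagram(
                conf, rec.gt_labels[region], rec.brain_mask,
                n_bins=n_bins, scope="subject", region=region,
            )
            rows.append(
                dict(
                    subject_id=rec.subject_id,
                    split=rec.split,
                    region=region,
                    ece=expected_calibration_error(diagram),
                    ace=average_calibration_error(diagram),
                    calibration_class=classify_subject_calibration(diagram, tolerance),
                )
            )
    subject_calibration = pd.DataFrame(rows)

    test = cohort.split("test") or list(cohort)
    validation = cohort.split("validation")
    if not validation:
        raise ValueError("threshold selection requires a non-empty validation split")

    dataset_diagrams: dict[str, ReliabilityDiagram] = {}
    ece_rows = []
    for region in regions:
        diagram = reliability_diagram(
            [confidence_map(r, region) for r in test],
            [r.gt_labels[region] for r in test],
            [r.brain_mask for r in test],
            n_bins=n_bins, scope="dataset", region=region,
        )
        dataset_diagrams[region] = diagram
        sub = subject_calibration.query("region == @region and ece == ece")
        sub_test = sub[sub.subject_id.isin([r.subject_id for r in test])]
        ece_rows.append(
            dict(
                region=region,
                dataset_ece=expected_calibration_error(diagram),
                mean_subject_ece=float(sub_test.ece.mean()),
                n_subjects=len(sub_test),
            )
        )

    selections = {
        region: select_threshold(method_id, validation, region, grid=threshold_grid)
        for region in regions
    }

    loc_rows = []
    for rec in test:
        for region in regions:
            q = subject_uncertainty(rec, region)
            e = error_map(rec.pred_labels[region], rec.gt_labels[region], region)
            t = selections[region].threshold
            loc_rows.append(
                dict(
                    subject_id=rec.subject_id,
                    region=region,
                    threshold=t,
                    ue_overlap=uncertainty_error_overlap(q, e, t, rec.brain_mask),
                    auc_pr=uncertainty_error_auc_pr(q, e, rec.brain_mask),
                    dice=dice_coefficient(rec.pred_labels[region], rec.gt_labels[region]),
                )
            )
    return VoxelEvaluation(
        subject_calibration=subject_calibration,
        dataset_diagrams=dataset_diagrams,
        dataset_ece=pd.DataFrame(ece_rows),
        threshold_selections=selections,
        test_localization=pd.DataFrame(loc_rows),
    )


# --------------------------------------------------------------------------
# subject-level failure detection
# --------------------------------------------------------------------------

@dataclass
class FailureAnalysis:
    """Outputs of the subject-level protocol."""

    features: pd.DataFrame  # long table: one row per subject×region×family
    dice: pd.DataFrame  # subject_id, split, region, dice
    summary: pd.DataFrame  # family × region metrics
    results: dict[tuple[str, str], FailureDetectionResult]
    regressors: dict[tuple[str, str], DiceRegressor]

    def write(self, out_dir: Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.features.to_csv(out_dir / "features.csv", index=False)
        self.dice.to_csv(out_dir / "dice.csv", index=False)
        self.summary.to_csv(out_dir / "failure_detection_summary.csv", index=False)
        roc_rows = []
        for (family, region), res in self.results.items():
            for f, t, thr in zip(res.fpr, res.tpr, res.thresholds):
                roc_rows.append(
                    dict(family=family, region=region, fpr=f, tpr=t, threshold=thr)
                )
        pd.DataFrame(roc_rows).to_csv(out_dir / "roc_curves.csv", index=False)
        imp = {
            f"{family}/{region}": reg.importances_
            for (family, region), reg in self.regressors.items()
        }
        (out_dir / "feature_importances.json").write_text(json.dumps(imp, indent=1))


def extract_features(
    cohort: Cohort,
    thresholds: Mapping[str, float],
    families: Sequence[str] = AGGREGATION_FAMILIES,
    regions: Sequence[str] | None = None,
) -> list[SubjectFeatures]:
    """Per-subject features for the requested aggregation families."""
    regions = tuple(regions or cohort.region_set)
    out: list[SubjectFeatures] = []
    for rec in cohort:
        for region in regions:
            q = subject_uncertainty(rec, region)
            if "mean" in families:
                out.append(
                    SubjectFeatures(
                        rec.subject_id,
                        region,
                        {"negative_mean_uncertainty": mean_aggregate(q, rec.brain_mask)},
                        family="mean",
                    )
                )
            if "prior_knowledge" in families:
                out.append(
                    prior_knowledge_features(
                        q, rec.pred_labels[region], rec.brain_mask, rec.spacing,
                        subject_id=rec.subject_id,
                    )
                )
            if "automatic" in families:
                out.append(
                    automatic_features(
                        q, thresholds[region], rec.spacing, rec.brain_mask,
                        subject_id=rec.subject_id,
                    )
                )
    return out


def detect_failures(
    cohort: Cohort,
    thresholds: Mapping[str, float],
    dice_cutoffs: Mapping[str, float],
    families: Sequence[str] = AGGREGATION_FAMILIES,
    regions: Sequence[str] | None = None,
    n_estimators: int = 500,
    random_state: int = 0,
) -> FailureAnalysis:
    """Aggregate, regress and score segmentation failure detection.

    Regressors (prior-knowledge and automatic families) are fitted on the
    training split and evaluated on the test split; the mean family needs no
    fitting.  Metrics are reported as NaN (undefined) when the test split is
    single-class.
    """
    regions = tuple(regions or cohort.region_set)
    for region in regions:
        if region not in dice_cutoffs:
            raise ValueError(
                f"no Dice cutoff configured for region {region}: per-region "
                "cutoffs are required (no hidden defaults)"
            )
    feats = extract_features(cohort, thresholds, families, regions)
    feat_table = features_frame(feats)

    dice_rows = [
        dict(
            subject_id=rec.subject_id,
            split=rec.split,
            region=region,
            dice=dice_coefficient(rec.pred_labels[region], rec.gt_labels[region]),
        )
        for rec in cohort
        for region in regions
    ]
    dice_table = pd.DataFrame(dice_rows)

    train_ids = [r.subject_id for r in cohort.split("train")]
    test_ids = [r.subject_id for r in cohort.split("test")] or [
        r.subject_id for r in cohort
    ]

    results: dict[tuple[str, str], FailureDetectionResult] = {}
    regressors: dict[tuple[str, str], DiceRegressor] = {}
    summary_rows = []
    for family in families:
        for region in regions:
            block = feat_table.query("family == @family and region == @region")
            block = block.set_index("subject_id")
            # the long table unions columns across families; keep only the
            # columns this family actually produced
            cols = [
                c for c in block.columns
                if c not in ("region", "family") and not block[c].isna().all()
            ]
            d = dice_table.query("region == @region").set_index("subject_id").dice

            if family == "mean":
                scores = block.loc[test_ids, "negative_mean_uncertainty"].to_numpy(
                    dtype=float
                )
            else:
                if len(train_ids) < 10:
                    raise ValueError(
                        f"{family}/{region}: need >= 10 training subjects, "
                        f"got {len(train_ids)}"
                    )
                reg = DiceRegressor(
                    n_estimators=n_estimators, random_state=random_state
                )
                reg.fit(block.loc[train_ids, cols], d.loc[train_ids].to_numpy())
                regressors[(family, region)] = reg
                scores = reg.predict(block.loc[test_ids, cols])

            res = evaluate_failure_detection(
                scores, d.loc[test_ids].to_numpy(), dice_cutoffs[region], region
            )
            results[(family, region)] = res
            row = dict(family=family, **res.summary())
            summary_rows.append(row)

    return FailureAnalysis(
        features=feat_table,
        dice=dice_table,
        summary=pd.DataFrame(summary_rows),
        results=results,
        regressors=regressors,
    )
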