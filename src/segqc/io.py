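"""NIfTI volume and cohort-manifest input/output.

Volumes are stored as ``.nii``/``.nii.gz`` with a diagonal affine built from
the voxel spacing.  A cohort lives in a directory with a ``manifest.csv``
holding one row per subject: ``subject_id``, ``split``, one path column per
volume role (relative to the manifest), and any extra metadata columns
(e.g. the synthetic generator's ``tau``, ``failure_mode``,
``true_dice_<region>``).

Volume role columns follow the pattern ``gt_<region>``, ``pred_<region>``,
``prob_<region>``, ``unc_<region>`` plus ``brain_mask``; alternatively a
single ``gt`` column may point to a sub-compartment-coded volume that is
combined into hierarchical regions on load.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .datamodel import (
    Cohort,
    SubjectRecord,
    UncertaintyMap,
    combine_hierarchical_labels,
)

_SPACING_ATOL = 1e-4


def save_volume(volume: np.ndarray, spacing, path: Path) -> None:
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def load_volume(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def load_subject(
    paths: Mapping[str, Path | str],
    subject_id: str = "subject",
    split: str = "test",
    codes: Mapping[str, int] | None = None,
    brain_mask_fallback: str = "error",
) -> SubjectRecord:
    """Assemble a SubjectRecord from per-volume file paths.

    ``paths`` maps volume roles (see module docstring) to files.  Shapes and
    spacings are validated against each other; a missing ``brain_mask`` role
    is an error unless ``brain_mask_fallback="ones"`` (all-ones mask).
    """
    loaded: dict[str, tuple[np.ndarray, tuple]] = {}
    for role, p in paths.items():
        if p is None or (isinstance(p, float) and np.isnan(p)):
            continue
        loaded[role] = load_volume(Path(p))
    if not loaded:
        raise ValueError(f"subject {subject_id}: no volumes given")
    ref_role = next(iter(loaded))
    ref_vol, ref_spacing = loaded[ref_role]
    for role, (vol, spacing) in loaded.items():
        if vol.shape != ref_vol.shape:
            raise ValueError(
                f"subject {subject_id}: shape mismatch between {ref_role} "
                f"{ref_vol.shape} and {role} {vol.shape}"
            )
        if not np.allclose(spacing, ref_spacing, atol=_SPACING_ATOL):
            raise ValueError(
                f"subject {subject_id}: spacing mismatch between {ref_role} "
                f"{ref_spacing} and {role} {spacing}"
            )

    if "brain_mask" in loaded:
        brain = loaded.pop("brain_mask")[0].astype(bool)
    elif brain_mask_fallback == "ones":
        brain = np.ones(ref_vol.shape, dtype=bool)
    else:
        raise ValueError(
            f"subject {subject_id}: brain_mask missing and fallback disabled"
        )

    gt: dict[str, np.ndarray] = {}
    pred: dict[str, np.ndarray] = {}
    prob: dict[str, np.ndarray] = {}
    unc: dict[str, UncertaintyMap] = {}
    for role, (vol, _) in loaded.items():
        if role == "gt":
            gt.update(combine_hierarchical_labels(vol, codes))
        elif role.startswith("gt_"):
            gt[role[3:]] = vol.astype(bool)
        elif role.startswith("pred_"):
            pred[role[5:]] = vol.astype(bool)
        elif role.startswith("prob_"):
            region = role[5:]
            v = vol.astype(float)
            if v.min() < 0 or v.max() > 1:
                raise ValueError(
                    f"subject {subject_id}: prob_{region} outside [0, 1] "
                    f"(range [{v.min()}, {v.max()}])"
                )
            prob[region] = v
        elif role.startswith("unc_"):
            region = role[4:]
            unc[region] = UncertaintyMap(
                vol.astype(float), provenance="native", region=region
            )
        else:
            raise ValueError(f"subject {subject_id}: unknown volume role {role!r}")

    record = SubjectRecord(
        subject_id=subject_id,
        spacing=ref_spacing,
        brain_mask=brain,
        gt_labels=gt,
        pred_labels=pred,
        prob_maps=prob or None,
        uncertainty_maps=unc or None,
        split=split,
    )
    record.validate()
    return record


def write_subject(record: SubjectRecord, directory: Path) -> dict[str, str]:
    """Write all volumes of one subject; returns role -> relative path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rel: dict[str, str] = {}

    def _save(role: str, volume: np.ndarray) -> None:
        fname = f"{record.subject_id}_{role}.nii.gz"
        save_volume(volume, record.spacing, directory / fname)
        rel[role] = fname

    _save("brain_mask", record.brain_mask)
    for region, v in record.gt_labels.items():
        _save(f"gt_{region}", v)
    for region, v in record.pred_labels.items():
        _save(f"pred_{region}", v)
    for region, v in (record.prob_maps or {}).items():
        _save(f"prob_{region}", v)
    for region, u in (record.uncertainty_maps or {}).items():
        _save(f"unc_{region}", u.values)
        sidecar = directory / f"{record.subject_id}_unc_{region}.json"
        sidecar.write_text(
            json.dumps({"provenance": u.provenance, "region": region})
        )
    return rel


def write_cohort(
    cohort: Cohort, directory: Path, manifest_extra: pd.DataFrame | None = None
) -> Path:
    """Write all subjects plus ``manifest.csv``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        rel = write_subject(rec, directory / rec.subject_id)
        row = {"subject_id": rec.subject_id, "split": rec.split}
        row.update({role: f"{rec.subject_id}/{p}" for role, p in rel.items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if manifest_extra is not None:
        extra = manifest_extra.drop(
            columns=[c for c in ("split",) if c in manifest_extra], errors="ignore"
        )
        manifest = manifest.merge(extra, on="subject_id", how="left")
    path = directory / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def load_cohort(
    manifest_path: Path,
    codes: Mapping[str, int] | None = None,
    brain_mask_fallback: str = "error",
) -> tuple[Cohort, pd.DataFrame]:
    """Load a cohort from a manifest CSV (paths relative to the manifest)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    role_cols = [
        c
        for c in manifest.columns
        if c == "brain_mask"
        or c == "gt"
        or c.startswith(("gt_", "pred_", "prob_", "unc_"))
    ]
    if not role_cols:
        raise ValueError(f"manifest {manifest_path} has no volume path columns")
    subjects = []
    for _, row in manifest.iterrows():
        paths = {
            role: base / str(row[role])
            for role in role_cols
            if isinstance(row[role], str)
        }
        subjects.append(
            load_subject(
                paths,
                subject_id=str(row["subject_id"]),
                split=str(row.get("split", "test")),
                codes=codes,
                brain_mask_fallback=brain_mask_fallback,
            )
        )
    regions = tuple(sorted({r for s in subjects for r in s.regions},
                           key=lambda r: ("WT", "TC", "ET").index(r) if r in ("WT", "TC", "ET") else 99))
    return Cohort(subjects, region_set=regions), manifest
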