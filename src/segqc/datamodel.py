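"""Cohort data model for segmentation-uncertainty quality assessment.

The toolkit evaluates voxel-wise uncertainty estimates of (brain tumor)
segmentations.  Ground truth and predictions are expressed over three nested
hierarchical tumor regions:

* ``WT`` (whole tumor)      = edema ∪ enhancing tumor ∪ necrosis/non-enhancing
* ``TC`` (tumor core)       = enhancing tumor ∪ necrosis/non-enhancing
* ``ET`` (enhancing tumor)  = enhancing tumor

so that ET ⊆ TC ⊆ WT.  Each region is evaluated independently through a
binary foreground mask; probability and uncertainty maps are per-region
scalar fields in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np

#: Canonical hierarchical region names, outermost first.
REGIONS: tuple[str, ...] = ("WT", "TC", "ET")

#: Default integer codes of the tumor sub-compartments (BraTS convention).
DEFAULT_SUBCOMPARTMENT_CODES: dict[str, int] = {"NCR_NET": 1, "ED": 2, "ET": 4}

#: Tolerance for values expected to lie in [0, 1].
UNIT_INTERVAL_ATOL = 1e-9


def _as_bool(volume: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(volume)
    if arr.dtype == bool:
        return arr
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{name} must be binary; found values {uniq[:10]}")
    return arr.astype(bool)


@dataclass
class UncertaintyMap:
    """Voxel-wise scalar uncertainty field in [0, 1].

    Parameters
    ----------
    values
        Uncertainty volume; finite, within [0, 1] up to a 1e-9 tolerance.
    provenance
        ``"entropy_from_prob"`` for maps derived from foreground
        probabilities via normalized entropy, ``"native"`` for maps produced
        directly by an uncertainty method (e.g. normalized variance or an
        auxiliary error-probability head).
    region
        Hierarchical region the map refers to.
    """

    values: np.ndarray
    provenance: str = "native"
    region: str = "WT"

    _PROVENANCES = ("entropy_from_prob", "native")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.provenance not in self._PROVENANCES:
            raise ValueError(
                f"provenance must be one of {self._PROVENANCES}, got {self.provenance!r}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("uncertainty map contains non-finite values")
        lo, hi = float(self.values.min(initial=0.0)), float(self.values.max(initial=0.0))
        if lo < -UNIT_INTERVAL_ATOL or hi > 1.0 + UNIT_INTERVAL_ATOL:
            raise ValueError(f"uncertainty values outside [0, 1]: range [{lo}, {hi}]")
        np.clip(self.values, 0.0, 1.0, out=self.values)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


def combine_hierarchical_labels(
    subcompartments: np.ndarray,
    codes: Mapping[str, int] | None = None,
) -> dict[str, np.ndarray]:
    """Combine a sub-compartment-coded label volume into hierarchical regions.

    WT is the union of all sub-compartments (ED, ET, NCR/NET), TC combines
    ET and NCR/NET, and ET is the ET sub-compartment alone, guaranteeing
    ET ⊆ TC ⊆ WT by construction.

    Parameters
    ----------
    subcompartments
        Integer-coded volume containing only the configured codes and 0.
    codes
        Mapping with keys ``NCR_NET``, ``ED``, ``ET``; defaults to the BraTS
        convention (1, 2, 4).

    Returns
    -------
    dict mapping region name -> boolean volume.
    """
    codes = dict(DEFAULT_SUBCOMPARTMENT_CODES if codes is None else codes)
    missing = {"NCR_NET", "ED", "ET"} - codes.keys()
    if missing:
        raise ValueError(f"codes mapping lacks sub-compartments: {sorted(missing)}")
    vol = np.asarray(subcompartments)
    allowed = np.array([0, codes["NCR_NET"], codes["ED"], codes["ET"]])
    unknown = np.setdiff1d(np.unique(vol), allowed)
    if unknown.size:
        raise ValueError(f"unknown sub-compartment codes in volume: {unknown.tolist()}")
    ncr, ed, et = vol == codes["NCR_NET"], vol == codes["ED"], vol == codes["ET"]
    return {"WT": ncr | ed | et, "TC": ncr | et, "ET": et}


def decompose_hierarchical_labels(
    labels: Mapping[str, np.ndarray],
    codes: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Inverse of :func:`combine_hierarchical_labels` on valid hierarchies.

    NCR/NET = TC ∖ ET and ED = WT ∖ TC; raises if the hierarchy is broken.
    """
    codes = dict(DEFAULT_SUBCOMPARTMENT_CODES if codes is None else codes)
    wt = _as_bool(labels["WT"], "WT")
    tc = _as_bool(labels["TC"], "TC")
    et = _as_bool(labels["ET"], "ET")
    if np.any(et & ~tc) or np.any(tc & ~wt):
        raise ValueError("label hierarchy broken: requires ET ⊆ TC ⊆ WT")
    out = np.zeros(wt.shape, dtype=np.int16)
    out[wt & ~tc] = codes["ED"]
    out[tc & ~et] = codes["NCR_NET"]
    out[et] = codes["ET"]
    return out


@dataclass
class SubjectRecord:
    """All per-subject volumes plus voxel spacing and split assignment.

    All volumes share one grid; masks are stored over the full grid and the
    brain mask is passed explicitly to metric operations rather than
    pre-cropping.  Coordinates are 0-based voxel indices; ``spacing`` (mm per
    axis) is used only by distance- and shape-based computations.
    """

    subject_id: str
    spacing: tuple[float, float, float]
    brain_mask: np.ndarray
    gt_labels: dict[str, np.ndarray]
    pred_labels: dict[str, np.ndarray]
    prob_maps: dict[str, np.ndarray] | None = None
    uncertainty_maps: dict[str, UncertaintyMap] | None = None
    split: str = "test"

    _SPLITS = ("train", "validation", "test")

    def __post_init__(self) -> None:
        if self.split not in self._SPLITS:
            raise ValueError(f"split must be one of {self._SPLITS}, got {self.split!r}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        self.brain_mask = _as_bool(self.brain_mask, "brain_mask")
        for role, vols in (("gt", self.gt_labels), ("pred", self.pred_labels)):
            for region, v in vols.items():
                vols[region] = _as_bool(v, f"{role}[{region}]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.brain_mask.shape

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.gt_labels)

    def validate(self, check_hierarchy: bool = False) -> None:
        """Check shared shape, value ranges and brain-mask support.

        ``check_hierarchy`` additionally asserts ET ⊆ TC ⊆ WT on the ground
        truth; predictions are never repaired nor required to nest (three
        independent foreground heads may break nesting).
        """
        shape = self.shape
        volumes: list[tuple[str, np.ndarray]] = []
        for region, v in self.gt_labels.items():
            volumes.append((f"gt[{region}]", v))
        for region, v in self.pred_labels.items():
            volumes.append((f"pred[{region}]", v))
        for region, v in (self.prob_maps or {}).items():
            volumes.append((f"prob[{region}]", v))
        for region, u in (self.uncertainty_maps or {}).items():
            volumes.append((f"uncertainty[{region}]", u.values))
        for name, v in volumes:
            if v.shape != shape:
                raise ValueError(
                    f"subject {self.subject_id}: shape mismatch between brain_mask "
                    f"{shape} and {name} {v.shape}"
                )
        for region, p in (self.prob_maps or {}).items():
            if p.min() < -UNIT_INTERVAL_ATOL or p.max() > 1.0 + UNIT_INTERVAL_ATOL:
                raise ValueError(
                    f"subject {self.subject_id}: prob[{region}] outside [0, 1] "
                    f"(range [{p.min()}, {p.max()}])"
                )
        for role, vols in (("gt", self.gt_labels), ("pred", self.pred_labels)):
            for region, v in vols.items():
                if np.any(v & ~self.brain_mask):
                    raise ValueError(
                        f"subject {self.subject_id}: {role}[{region}] extends "
                        "outside the brain mask"
                    )
        if check_hierarchy and all(r in self.gt_labels for r in REGIONS):
            decompose_hierarchical_labels(self.gt_labels)


@dataclass
class Cohort:
    """Ordered collection of subjects sharing one region set."""

    subjects: list[SubjectRecord]
    region_set: tuple[str, ...] = REGIONS

    def __post_init__(self) -> None:
        self.region_set = tuple(self.region_set)
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject_ids in cohort: {dupes}")
        for s in self.subjects:
            extra = set(self.region_set) - set(s.regions)
            if extra:
                raise ValueError(
                    f"subject {s.subject_id} lacks regions {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def __getitem__(self, key: int | str) -> SubjectRecord:
        if isinstance(key, str):
            for s in self.subjects:
                if s.subject_id == key:
                    return s
            raise KeyError(key)
        return self.subjects[key]

    def split(self, name: str) -> list[SubjectRecord]:
        """Subjects assigned to one of train/validation/test."""
        if name not in SubjectRecord._SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return [s for s in self.subjects if s.split == name]
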