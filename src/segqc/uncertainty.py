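"""Voxel-wise uncertainty and confidence construction.

Uncertainty maps arise from three sources: the normalized entropy of a
foreground probability map, the mean of a stack of probability samples
(Monte-Carlo dropout draws or ensemble members) again passed through the
normalized entropy, or an uncertainty-native map (e.g. an aleatoric variance
volume or an auxiliary network's error probability) rescaled to [0, 1] with
cohort-global extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import UNIT_INTERVAL_ATOL, UncertaintyMap

#: Probabilities are clamped to [EPS, 1-EPS] before taking logs; the
#: 0·log 0 = 0 convention then holds exactly at the endpoints below EPS.
EPS = 1e-12


def _check_unit_interval(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{name} contains non-finite values")
    if p.min(initial=0.0) < -UNIT_INTERVAL_ATOL or p.max(initial=0.0) > 1 + UNIT_INTERVAL_ATOL:
        raise ValueError(
            f"{name} outside [0, 1]: range [{p.min()}, {p.max()}]"
        )
    return np.clip(p, 0.0, 1.0)


def normalized_entropy(p: np.ndarray, region: str = "WT") -> UncertaintyMap:
    """Normalized binary entropy H = −[p·log p + (1−p)·log(1−p)] / log 2.

    H is 1 at p = 0.5 (maximal uncertainty) and 0 at p ∈ {0, 1}, symmetric
    under p ↦ 1−p, and strictly increasing on [0, 0.5].
    """
    p = _check_unit_interval(p, "p")
    pc = np.clip(p, EPS, 1.0 - EPS)
    h = -(pc * np.log(pc) + (1.0 - pc) * np.log1p(-pc)) / np.log(2.0)
    h[(p <= EPS) | (p >= 1.0 - EPS)] = 0.0
    np.clip(h, 0.0, 1.0, out=h)
    return UncertaintyMap(h, provenance="entropy_from_prob", region=region)


@dataclass
class SampleStack:
    """T probability volumes from a sampling or ensemble method."""

    samples: np.ndarray  # (T, *grid)
    region: str = "WT"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim < 2 or self.samples.shape[0] < 1:
            raise ValueError("stack must hold T >= 1 volumes of equal shape")
        _check_unit_interval(self.samples, "samples")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])


def combine_samples(stack: SampleStack) -> np.ndarray:
    """Voxel-wise arithmetic mean probability p = (1/T) Σ_t p_t.

    The entropy of this mean — not the variance of the samples — is the
    uncertainty measure used downstream.
    """
    return np.clip(stack.samples.mean(axis=0), 0.0, 1.0)


@dataclass(frozen=True)
class CohortExtrema:
    """Cohort-global min/max of a native uncertainty quantity for a region.

    Native maps (e.g. aleatoric variance) are normalized over *all subjects*
    of a cohort, never per subject; the cohort whose extrema apply is an
    explicit argument of :func:`normalize_native_map`.
    """

    vmin: float
    vmax: float
    region: str = "WT"

    @classmethod
    def from_volumes(cls, volumes, region: str = "WT") -> "CohortExtrema":
        vols = list(volumes)
        if not vols:
            raise ValueError("cannot compute extrema of an empty cohort")
        vmin = min(float(np.min(v)) for v in vols)
        vmax = max(float(np.max(v)) for v in vols)
        return cls(vmin=vmin, vmax=vmax, region=region)


def normalize_native_map(
    values: np.ndarray, cohort_context: CohortExtrema
) -> UncertaintyMap:
    """Min-max rescale a native map with cohort-global extrema.

    A cohort with constant values (zero range) maps to all-zeros by
    convention.
    """
    if cohort_context is None:
        raise ValueError(
            "cohort_context is required: native maps are normalized over all "
            "subjects of a cohort, not per subject"
        )
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("native map contains non-finite values")
    if values.min(initial=0.0) < 0:
        raise ValueError("native map must be non-negative")
    rng = cohort_context.vmax - cohort_context.vmin
    if rng <= 0:
        out = np.zeros_like(values)
    else:
        out = np.clip((values - cohort_context.vmin) / rng, 0.0, 1.0)
    return UncertaintyMap(out, provenance="native", region=cohort_context.region)


def uncertainty_to_confidence(q: UncertaintyMap, y: np.ndarray) -> np.ndarray:
    """Translate uncertainty q and predicted label y to a foreground-probability
    surrogate: y·(1 − 0.5q) + (1 − y)·0.5q.

    Predicted-foreground voxels map to [0.5, 1], predicted-background to
    [0, 0.5], so the result is coherent on a foreground-probability
    (calibration-curve) confidence axis.
    """
    y = np.asarray(y)
    if y.shape != q.values.shape:
        raise ValueError(f"shape mismatch: q {q.values.shape} vs y {y.shape}")
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"y must be binary; found values {uniq[:10]}")
    yf = y.astype(float)
    return yf * (1.0 - 0.5 * q.values) + (1.0 - yf) * (0.5 * q.values)
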