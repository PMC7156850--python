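"""Subject-level aggregation of voxel-wise uncertainty.

Three aggregation families reduce an uncertainty map to per-subject
information whose quality is judged by how well it tracks the Dice
coefficient of the segmentation:

* ``mean`` — the negative mean uncertainty inside the brain mask (one
  scalar; larger = predicted better).
* ``prior_knowledge`` — nine features: three boundary-aware weightings of
  the uncertainty map (boundary-masked, distance-weighted-masked,
  volume-normalized), each reduced by mean, sum and logsum.  Segmentation
  boundaries carry inherent, size-proportional uncertainty even for good
  segmentations, so these weightings deemphasize it.
* ``automatic`` — a configurable panel of shape / first-order / gray-level
  run-length features of the thresholded uncertainty map (see
  :mod:`segqc.texture`).

A random forest regressor (:class:`DiceRegressor`) maps a feature family to
a predicted Dice coefficient; feature importances are compared across models
by rank accumulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor

from .datamodel import UncertaintyMap, _as_bool

#: Face-connected (city-block) 3D structuring element.
_STRUCT = ndimage.generate_binary_structure(3, 1)

PRIOR_WEIGHTINGS = ("boundary_masked", "distance_weighted_masked", "volume_normalized")
PRIOR_REDUCERS = ("mean", "sum", "logsum")
PRIOR_FEATURE_NAMES = tuple(
    f"{w}_{r}" for w in PRIOR_WEIGHTINGS for r in PRIOR_REDUCERS
)


@dataclass
class SubjectFeatures:
    """Named scalar aggregates for one subject and region."""

    subject_id: str
    region: str
    features: dict[str, float]
    family: str  # mean | prior_knowledge | automatic

    def __post_init__(self) -> None:
        if self.family not in ("mean", "prior_knowledge", "automatic"):
            raise ValueError(f"unknown feature family {self.family!r}")


def features_frame(rows: Sequence[SubjectFeatures]) -> pd.DataFrame:
    """Stack per-subject features into a table (one row per subject)."""
    recs = []
    for r in rows:
        rec = {"subject_id": r.subject_id, "region": r.region, "family": r.family}
        rec.update(r.features)
        recs.append(rec)
    return pd.DataFrame(recs)


def mean_aggregate(q: UncertaintyMap, mask: np.ndarray) -> float:
    """Negative mean uncertainty inside the mask (larger = predicted better)."""
    m = _as_bool(mask, "mask")
    if not m.any():
        raise ValueError("empty mask in mean aggregation")
    return -float(q.values[m].mean())


def boundary_band(pred: np.ndarray) -> np.ndarray:
    """Three-voxel band around the predicted surface.

    The band holds the boundary voxels (outermost foreground layer) plus
    their immediate inner and outer shells at face-connected distance 1:
    dilation by one minus erosion by two.  An empty prediction yields an
    empty band.
    """
    pred = _as_bool(pred, "pred")
    if not pred.any():
        return np.zeros_like(pred)
    dil = ndimage.binary_dilation(pred, structure=_STRUCT)
    ero2 = ndimage.binary_erosion(pred, structure=_STRUCT, iterations=2)
    return dil & ~ero2


def _logsum(total: float) -> float:
    # log(1 + Σ) keeps the reducer finite on empty support.
    return float(np.log1p(total))


def prior_knowledge_features(
    q: UncertaintyMap,
    pred: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    subject_id: str = "",
) -> SubjectFeatures:
    """Nine prior-knowledge aggregates: 3 weightings × {mean, sum, logsum}.

    Weightings (all supported on the evaluation mask):

    * boundary-masked: q zeroed on the 3-voxel boundary band;
    * distance-weighted-masked: the boundary-masked map multiplied by the
      unsigned Euclidean distance (mm) to the predicted surface, penalizing
      boundary-adjacent and up-weighting remote uncertainty;
    * volume-normalized: q divided by the predicted volume in voxels.

    With an empty prediction the distance- and volume-based weightings are
    undefined; their features are recorded as NaN and imputed (0 plus a
    missingness indicator) by :class:`DiceRegressor`.
    """
    pred = _as_bool(pred, "pred")
    m = _as_bool(mask, "mask")
    if not m.any():
        raise ValueError("empty evaluation mask")
    if q.values.shape != pred.shape or pred.shape != m.shape:
        raise ValueError("q, pred and mask must share one shape")
    n_mask = int(m.sum())

    feats: dict[str, float] = {}

    band = boundary_band(pred)
    masked = np.where(band, 0.0, q.values)
    s = float(masked[m].sum())
    feats["boundary_masked_mean"] = s / n_mask
    feats["boundary_masked_sum"] = s
    feats["boundary_masked_logsum"] = _logsum(s)

    if pred.any():
        surface = pred & ~ndimage.binary_erosion(pred, structure=_STRUCT)
        dist = ndimage.distance_transform_edt(~surface, sampling=spacing)
        wd = masked * dist
        s = float(wd[m].sum())
        feats["distance_weighted_masked_mean"] = s / n_mask
        feats["distance_weighted_masked_sum"] = s
        feats["distance_weighted_masked_logsum"] = _logsum(s)

        vol = int(pred.sum())
        s = float(q.values[m].sum()) / vol
        feats["volume_normalized_mean"] = s / n_mask
        feats["volume_normalized_sum"] = s
        feats["volume_normalized_logsum"] = _logsum(s)
    else:
        for w in ("distance_weighted_masked", "volume_normalized"):
            for r in PRIOR_REDUCERS:
                feats[f"{w}_{r}"] = float("nan")

    ordered = {name: feats[name] for name in PRIOR_FEATURE_NAMES}
    return SubjectFeatures(subject_id, q.region, ordered, family="prior_knowledge")


class DiceRegressor(RegressorMixin, BaseEstimator):
    """Random-forest regressor predicting the Dice coefficient of a subject.

    scikit-learn-compatible estimator over a feature table.  Missing values
    (undefined features, e.g. from empty predictions) are imputed with 0 and
    flagged with a per-column missingness indicator fitted on the training
    table; prediction refuses feature tables whose columns mismatch
    training.  Predictions are clipped to [0, 1].

    Parameters
    ----------
    n_estimators
        Forest size; 500 by default.
    random_state
        Seed recorded with the model; refitting with the same seed and data
        reproduces identical predictions.
    max_features, min_samples_leaf
        Passed through to :class:`sklearn.ensemble.RandomForestRegressor`.
    """

    def __init__(
        self,
        n_estimators: int = 500,
        random_state: int | None = 0,
        max_features: float | str = 1.0,
        min_samples_leaf: int = 1,
    ) -> None:
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf

    # -- internal ---------------------------------------------------------
    def _augment(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        if list(X.columns) != list(self.feature_names_):
            raise ValueError(
                f"feature name mismatch: expected {list(self.feature_names_)}, "
                f"got {list(X.columns)}"
            )
        blocks = [X.fillna(0.0).to_numpy(dtype=float)]
        for col in self.missing_indicator_columns_:
            blocks.append(X[col].isna().to_numpy(dtype=float)[:, None])
        return np.hstack(blocks)

    # -- sklearn API ------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "DiceRegressor":
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"f{i}" for i in range(X.shape[1])]
        y = np.asarray(y, dtype=float)
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        if len(X) < 10:
            raise ValueError(f"need at least 10 training subjects, got {len(X)}")
        if np.ptp(y) == 0:
            raise ValueError(
                "constant training target: the Dice coefficient does not vary, "
                "a regressor cannot be fitted"
            )
        self.feature_names_ = tuple(X.columns)
        self.missing_indicator_columns_ = tuple(
            c for c in X.columns if X[c].isna().any()
        )
        Xa = self._augment(X, fitting=True)
        use_oob = len(X) >= 15
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_estimators,
            random_state=self.random_state,
            max_features=self.max_features,
            min_samples_leaf=self.min_samples_leaf,
            oob_score=use_oob,
        )
        self.model_.fit(Xa, y)
        self.oob_score_ = float(self.model_.oob_score_) if use_oob else float("nan")
        names = list(self.feature_names_) + [
            f"{c}__missing" for c in self.missing_indicator_columns_
        ]
        self.importances_ = dict(
            zip(names, self.model_.feature_importances_.tolist())
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise ValueError("regressor is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=list(self.feature_names_))
        return np.clip(self.model_.predict(self._augment(X, fitting=False)), 0.0, 1.0)

    def feature_importance_ranks(self) -> dict[str, int]:
        """Dense ranks of the base features, 1 = most important.

        Missingness-indicator columns are excluded from ranking.
        """
        items = [(n, self.importances_[n]) for n in self.feature_names_]
        order = sorted(items, key=lambda kv: (-kv[1], kv[0]))
        return {name: rank for rank, (name, _) in enumerate(order, start=1)}


def fit_dice_regressor(
    train_features: pd.DataFrame,
    train_dice,
    n_estimators: int = 500,
    random_state: int | None = 0,
    **kwargs,
) -> DiceRegressor:
    """Convenience wrapper building and fitting a :class:`DiceRegressor`."""
    reg = DiceRegressor(
        n_estimators=n_estimators, random_state=random_state, **kwargs
    )
    return reg.fit(train_features, train_dice)


def rank_accumulate_importance(
    models: Sequence[DiceRegressor],
) -> list[tuple[str, int]]:
    """Accumulate per-model importance ranks into one overall feature order.

    Each model contributes the rank (1 = most important) of every feature;
    features are ordered by ascending total rank, ties broken
    alphabetically.  All models must share one feature set.
    """
    if not models:
        raise ValueError("no models to accumulate")
    names = set(models[0].feature_names_)
    for m in models[1:]:
        if set(m.feature_names_) != names:
            raise ValueError("models have mismatched feature sets")
    totals: dict[str, int] = {n: 0 for n in names}
    for m in models:
        for name, rank in m.feature_importance_ranks().items():
            totals[name] += rank
    return sorted(totals.items(), key=lambda kv: (kv[1], kv[0]))
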