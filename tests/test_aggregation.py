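"""Subject-level aggregation: weightings, reducers, shape/texture features,
Dice regression and importance ranking."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from segqc.aggregation import (
    DiceRegressor,
    boundary_band,
    fit_dice_regressor,
    mean_aggregate,
    prior_knowledge_features,
    rank_accumulate_importance,
    PRIOR_FEATURE_NAMES,
)
from segqc.datamodel import UncertaintyMap
from segqc.texture import (
    automatic_features,
    run_length_matrix,
    run_length_non_uniformity,
    shape_features,
    sphericity,
    discretize,
)


def qmap(values, region="WT"):
    return UncertaintyMap(np.asarray(values, dtype=float), provenance="native",
                          region=region)


class TestMeanAggregate:
    @pytest.mark.parametrize("c,expected", [(0.0, 0.0), (1.0, -1.0), (0.25, -0.25)])
    def test_constant_fields(self, c, expected):
        mask = np.ones((3, 3, 3), dtype=bool)
        assert mean_aggregate(qmap(np.full((3, 3, 3), c)), mask) == pytest.approx(expected)

    def test_invariant_to_voxels_outside_mask(self, rng):
        q = rng.random((4, 4, 4))
        mask = rng.random((4, 4, 4)) < 0.5
        q2 = q.copy()
        q2[~mask] = rng.random((~mask).sum())
        assert mean_aggregate(qmap(q), mask) == pytest.approx(mean_aggregate(qmap(q2), mask))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_aggregate(qmap(np.zeros((2, 2, 2))), np.zeros((2, 2, 2), dtype=bool))


def band_oracle(pred):
    """Surface voxels plus their face neighbors, by explicit enumeration."""
    pred = pred.astype(bool)
    surface = np.zeros_like(pred)
    nbrs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for idx in np.argwhere(pred):
        for d in nbrs:
            j = idx + d
            if np.any(j < 0) or np.any(j >= pred.shape) or not pred[tuple(j)]:
                surface[tuple(idx)] = True
                break
    band = surface.copy()
    for idx in np.argwhere(surface):
        for d in nbrs:
            j = idx + d
            if np.all(j >= 0) and np.all(j < pred.shape):
                band[tuple(j)] = True
    return band


class TestBoundaryBand:
    def test_single_voxel_gives_face_neighborhood(self):
        pred = np.zeros((5, 5, 5), dtype=bool)
        pred[2, 2, 2] = True
        np.testing.assert_array_equal(boundary_band(pred), band_oracle(pred))
        assert boundary_band(pred).sum() == 7

    def test_cube_band_is_faces_plus_inner_and_outer_shells(self):
        pred = np.zeros((9, 9, 9), dtype=bool)
        pred[2:7, 2:7, 2:7] = True
        np.testing.assert_array_equal(boundary_band(pred), band_oracle(pred))

    def test_random_shapes_match_enumeration_oracle(self, rng):
        for _ in range(5):
            pred = ndimage.binary_closing(rng.random((8, 8, 8)) < 0.4)
            np.testing.assert_array_equal(boundary_band(pred), band_oracle(pred))

    def test_empty_prediction_gives_empty_band(self):
        assert not boundary_band(np.zeros((4, 4, 4), dtype=bool)).any()


class TestPriorKnowledgeFeatures:
    def _setup(self, shape=(16, 16, 16)):
        pred = np.zeros(shape, dtype=bool)
        pred[6:10, 6:10, 6:10] = True
        mask = np.ones(shape, dtype=bool)
        return pred, mask

    def test_feature_names_and_order(self):
        pred, mask = self._setup()
        f = prior_knowledge_features(qmap(np.zeros(pred.shape)), pred, mask, (1, 1, 1))
        assert tuple(f.features) == PRIOR_FEATURE_NAMES
        assert f.family == "prior_knowledge"

    def test_band_supported_uncertainty_zeroes_masked_reducers(self):
        pred, mask = self._setup()
        band = boundary_band(pred)
        q = np.where(band, 0.7, 0.0)
        f = prior_knowledge_features(qmap(q), pred, mask, (1, 1, 1)).features
        assert f["boundary_masked_mean"] == 0.0
        assert f["boundary_masked_sum"] == 0.0
        assert f["boundary_masked_logsum"] == 0.0

    def test_masked_features_invariant_to_band_content(self, rng):
        pred, mask = self._setup()
        band = boundary_band(pred)
        q = rng.random(pred.shape) * 0.5
        q2 = q.copy()
        q2[band] = rng.random(band.sum())
        f1 = prior_knowledge_features(qmap(q), pred, mask, (1, 1, 1)).features
        f2 = prior_knowledge_features(qmap(q2), pred, mask, (1, 1, 1)).features
        for name in PRIOR_FEATURE_NAMES:
            if name.startswith(("boundary_masked", "distance_weighted_masked")):
                assert f1[name] == pytest.approx(f2[name])

    def test_volume_normalized_sum_closed_form_on_constant_field(self):
        pred, mask = self._setup()
        c = 0.3
        f = prior_knowledge_features(qmap(np.full(pred.shape, c)), pred, mask, (1, 1, 1)).features
        expected = c * mask.sum() / pred.sum()
        assert f["volume_normalized_sum"] == pytest.approx(expected)

    def test_remote_blob_distance_doubles_contribution(self):
        """Doubling a remote uncertainty blob's distance doubles its
        distance-weighted contribution (two-blob phantom)."""
        shape = (48, 12, 12)
        pred = np.zeros(shape, dtype=bool)
        pred[2:5, 5:8, 5:8] = True
        mask = np.ones(shape, dtype=bool)
        base = prior_knowledge_features(qmap(np.zeros(shape)), pred, mask, (1, 1, 1)).features

        surface_x = 4  # outermost predicted slab
        near = np.zeros(shape)
        near[surface_x + 10, 6, 6] = 0.8
        far = np.zeros(shape)
        far[surface_x + 20, 6, 6] = 0.8
        f_near = prior_knowledge_features(qmap(near), pred, mask, (1, 1, 1)).features
        f_far = prior_knowledge_features(qmap(far), pred, mask, (1, 1, 1)).features
        ratio = (f_far["distance_weighted_masked_sum"] - base["distance_weighted_masked_sum"]) / (
            f_near["distance_weighted_masked_sum"] - base["distance_weighted_masked_sum"]
        )
        assert ratio == pytest.approx(2.0, rel=0.01)

    def test_empty_prediction_yields_missing_features(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        f = prior_knowledge_features(
            qmap(np.zeros((6, 6, 6))), np.zeros((6, 6, 6), dtype=bool), mask, (1, 1, 1)
        ).features
        assert np.isnan(f["distance_weighted_masked_mean"])
        assert np.isnan(f["volume_normalized_sum"])
        assert f["boundary_masked_sum"] == 0.0


def ball(radius, pad=3):
    n = 2 * (radius + pad) + 1
    c = (n - 1) / 2
    x, y, z = np.ogrid[:n, :n, :n]
    return (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= radius**2


class TestShapeFeatures:
    def test_ball_sphericity_near_one(self):
        f = shape_features(ball(12), (1, 1, 1))
        assert 0.95 <= f["shape_sphericity"] <= 1.05

    def test_cube_sphericity_matches_closed_form(self):
        cube = np.zeros((46, 46, 46), dtype=bool)
        cube[3:43, 3:43, 3:43] = True
        f = shape_features(cube, (1, 1, 1))
        expected = (np.pi / 6.0) ** (1.0 / 3.0)  # ≈ 0.806
        assert f["shape_sphericity"] == pytest.approx(expected, rel=0.02)

    def test_sphericity_bounded_for_random_shapes(self, rng):
        for _ in range(5):
            region = ndimage.binary_closing(rng.random((12, 12, 12)) < 0.4)
            if region.sum() < 10:
                continue
            f = shape_features(region, (1, 1, 1))
            assert f["shape_sphericity"] <= 1.05

    def test_component_count(self):
        two = ball(4, pad=2)
        region = np.concatenate([two, np.zeros_like(two), two], axis=0)
        assert shape_features(region, (1, 1, 1))["shape_n_components"] == 2.0

    def test_sphericity_formula(self):
        # sphere of radius r: V = 4/3 π r³, A = 4 π r² → sphericity 1
        r = 7.0
        assert sphericity(4 / 3 * np.pi * r**3, 4 * np.pi * r**2) == pytest.approx(1.0)


class TestRunLength:
    def test_hand_counted_toy_matrix(self):
        """One row with runs {(level 1, len 2), (level 2, len 1)} → RLN = 1."""
        values = np.array([[[0.01, 0.01, 0.07]]])  # levels 1, 1, 2 at width 0.05
        levels = discretize(values, np.ones_like(values, dtype=bool))
        mat = run_length_matrix(levels, direction=(0, 0, 1), n_levels=2)
        np.testing.assert_array_equal(mat, [[0, 1], [1, 0]])
        assert run_length_non_uniformity(mat) == pytest.approx(1.0)

    def test_runs_broken_by_mask(self):
        values = np.full((1, 1, 5), 0.02)
        mask = np.array([[[1, 1, 0, 1, 1]]], dtype=bool)
        levels = discretize(values, mask)
        mat = run_length_matrix(levels, (0, 0, 1))
        # two runs of length 2 at level 1
        assert mat[0, 1] == 2 and mat.sum() == 2

    def test_matrix_counts_match_manual_rle(self, rng):
        values = rng.choice([0.02, 0.27, 0.52], size=(1, 1, 30))
        mask = np.ones_like(values, dtype=bool)
        levels = discretize(values, mask)
        mat = run_length_matrix(levels, (0, 0, 1))
        flat = levels.ravel()
        runs = []
        start = 0
        for i in range(1, len(flat) + 1):
            if i == len(flat) or flat[i] != flat[start]:
                runs.append((flat[start], i - start))
                start = i
        manual = np.zeros_like(mat)
        for lv, ln in runs:
            manual[lv - 1, ln - 1] += 1
        np.testing.assert_array_equal(mat, manual)

    def test_diagonal_direction_supported(self):
        values = np.eye(4)[None] * 0.3
        mask = values > 0
        levels = discretize(values, mask)
        mat = run_length_matrix(levels, (0, 1, 1))
        # the four diagonal voxels form one run of length 4
        assert mat[int(0.3 / 0.05), 3] == 1


class TestAutomaticFeatures:
    def test_panel_contains_mandatory_features(self, rng):
        q = qmap(np.clip(rng.random((12, 12, 12)), 0, 1))
        f = automatic_features(q, 0.5, (1, 1, 1)).features
        for name in (
            "shape_volume_voxels", "shape_surface_area", "shape_sphericity",
            "firstorder_mean", "firstorder_variance", "firstorder_entropy",
            "firstorder_percentile10", "glrlm_run_length_non_uniformity",
        ):
            assert name in f and np.isfinite(f[name])

    def test_empty_thresholded_region_flagged_missing(self):
        f = automatic_features(qmap(np.zeros((6, 6, 6))), 0.5, (1, 1, 1)).features
        assert f and all(np.isnan(v) for v in f.values())


class TestDiceRegressor:
    def _table(self, rng, n=200, k=5):
        X = pd.DataFrame(
            rng.random((n, k)), columns=[f"feat_{i}" for i in range(k)]
        )
        return X

    def test_recovers_single_feature_signal(self, rng):
        X = self._table(rng)
        y = np.clip(X["feat_0"].to_numpy() * 0.8 + 0.1 + rng.normal(0, 0.01, len(X)), 0, 1)
        reg = fit_dice_regressor(X[:150], y[:150], n_estimators=200, random_state=0)
        from scipy.stats import spearmanr
        rho = spearmanr(reg.predict(X[150:]), y[150:]).statistic
        assert rho > 0.95
        ranks = reg.feature_importance_ranks()
        assert ranks["feat_0"] == 1

    def test_permuted_targets_give_no_signal(self, rng):
        X = self._table(rng)
        y = rng.permutation(np.linspace(0.1, 0.9, len(X)))
        reg = fit_dice_regressor(X[:150], y[:150], n_estimators=200, random_state=0)
        from scipy.stats import spearmanr
        rho = spearmanr(reg.predict(X[150:]), y[150:]).statistic
        assert abs(rho) < 0.25

    def test_refit_with_same_seed_is_deterministic(self, rng):
        X = self._table(rng, n=50)
        y = np.clip(X.sum(axis=1) / 5, 0, 1)
        p1 = fit_dice_regressor(X, y, n_estimators=100, random_state=7).predict(X)
        p2 = fit_dice_regressor(X, y, n_estimators=100, random_state=7).predict(X)
        np.testing.assert_array_equal(p1, p2)

    def test_predictions_clipped_to_unit_interval(self, rng):
        X = self._table(rng, n=30)
        y = np.linspace(0, 1, 30)
        reg = fit_dice_regressor(X, y, n_estimators=50)
        p = reg.predict(X)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_feature_name_mismatch_rejected(self, rng):
        X = self._table(rng, n=30)
        reg = fit_dice_regressor(X, np.linspace(0, 1, 30), n_estimators=10)
        with pytest.raises(ValueError, match="feature name mismatch"):
            reg.predict(X.rename(columns={"feat_0": "other"}))

    def test_constant_target_rejected(self, rng):
        X = self._table(rng, n=30)
        with pytest.raises(ValueError, match="constant"):
            fit_dice_regressor(X, np.full(30, 0.5))

    def test_too_few_subjects_rejected(self, rng):
        X = self._table(rng, n=5)
        with pytest.raises(ValueError, match="10"):
            fit_dice_regressor(X, np.linspace(0, 1, 5))

    def test_missing_values_imputed_with_indicator(self, rng):
        X = self._table(rng, n=40)
        X.loc[::5, "feat_1"] = np.nan
        y = np.clip(X["feat_0"], 0, 1)
        reg = fit_dice_regressor(X, y, n_estimators=50)
        assert "feat_1__missing" in reg.importances_
        assert np.isfinite(reg.predict(X)).all()


class TestRankAccumulation:
    def _model(self, importances):
        reg = DiceRegressor()
        reg.feature_names_ = tuple(importances)
        reg.importances_ = dict(importances)
        return reg

    def test_single_model_equals_its_own_order(self):
        m = self._model({"a": 0.5, "b": 0.3, "c": 0.2})
        assert [n for n, _ in rank_accumulate_importance([m])] == ["a", "b", "c"]

    def test_unanimous_top_feature_ranks_first(self):
        models = [
            self._model({"a": 0.6, "b": 0.3, "c": 0.1}),
            self._model({"a": 0.5, "b": 0.1, "c": 0.4}),
            self._model({"a": 0.9, "b": 0.05, "c": 0.05}),
        ]
        assert rank_accumulate_importance(models)[0][0] == "a"

    def test_three_models_match_hand_summed_ranks(self):
        models = [
            self._model({"a": 0.5, "b": 0.3, "c": 0.2}),  # ranks a1 b2 c3
            self._model({"a": 0.1, "b": 0.6, "c": 0.3}),  # ranks b1 c2 a3
            self._model({"a": 0.4, "b": 0.35, "c": 0.25}),  # ranks a1 b2 c3
        ]
        # totals: a=5, b=5, c=8; tie a/b broken alphabetically
        assert rank_accumulate_importance(models) == [("a", 5), ("b", 5), ("c", 8)]

    def test_mismatched_feature_sets_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rank_accumulate_importance(
                [self._model({"a": 1.0}), self._model({"b": 1.0})]
            )
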