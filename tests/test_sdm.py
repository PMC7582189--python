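"""Background sampling, train/test splitting, and the five base learners."""

import numpy as np
import pytest

from snakerisk import (METHODS, fit_sdm, sample_background, split_train_test)
from snakerisk.evaluation import auc
from snakerisk.predictors import PredictorMatrix
from snakerisk.raster import EnvStack, GridTransform
from snakerisk.sdm import SDM, SDMResults, _SklearnState, _Standardizer


def _toy_stack(n=20, mask=None) -> EnvStack:
    rng = np.random.default_rng(0)
    grids = {"a": rng.normal(size=(n, n)), "b": rng.normal(size=(n, n))}
    if mask is None:
        mask = np.zeros((n, n), dtype=bool)
    for g in grids.values():
        g[mask] = np.nan
    return EnvStack(["a", "b"], grids, mask, GridTransform(0, 0, 1, 1))


class TestSampleBackground:
    def test_count_and_determinism(self):
        stack = _toy_stack()
        bg1 = sample_background(stack, n=100, seed=1)
        bg2 = sample_background(stack, n=100, seed=1)
        assert len(bg1.points) == 100
        assert bg1.points == bg2.points

    def test_masked_half_excluded(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:, 10:] = True  # mask the right half
        stack = _toy_stack(mask=mask)
        bg = sample_background(stack, n=150, seed=0)
        assert all(x < 10 for x, _ in bg.points)

    def test_oversampling_warns_and_replaces(self):
        stack = _toy_stack(n=8)
        with pytest.warns(UserWarning, match="replacement"):
            bg = sample_background(stack, n=100, seed=0)
        assert len(bg.points) == 100


class TestSplitTrainTest:
    def test_eighty_twenty(self):
        split = split_train_test(10, 100, fraction=0.8, seed=0)
        assert len(split.train_presence_idx) == 8
        assert len(split.test_presence_idx) == 2
        assert len(split.train_background_idx) == 80

    def test_partition_is_exhaustive_and_disjoint(self):
        split = split_train_test(37, 500, fraction=0.8, seed=3)
        p = set(split.train_presence_idx) | set(split.test_presence_idx)
        assert p == set(range(37))
        assert not set(split.train_presence_idx) & set(split.test_presence_idx)
        b = set(split.train_background_idx) | set(split.test_background_idx)
        assert b == set(range(500))

    def test_deterministic(self):
        a = split_train_test(20, 50, seed=7)
        b = split_train_test(20, 50, seed=7)
        assert np.array_equal(a.train_presence_idx, b.train_presence_idx)
        assert np.array_equal(a.train_background_idx, b.train_background_idx)

    def test_too_few_presences_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            split_train_test(3, 100)


def _logistic_sim(n_pres=500, n_back=500, betas=(2.0, -2.0, 0.0), seed=0):
    """Presence/background matrices drawn from a logistic truth by
    rejection sampling of the presence class."""
    rng = np.random.default_rng(seed)
    k = len(betas)
    pool = rng.normal(size=(20 * n_pres, k))
    p = 1 / (1 + np.exp(-(pool @ np.asarray(betas))))
    keep = rng.random(len(p)) < p
    pres = pool[keep][:n_pres]
    back = rng.normal(size=(n_back, k))
    names = [f"x{i}" for i in range(k)]
    return (PredictorMatrix(names, pres, "occurrences"),
            PredictorMatrix(names, back, "background"))


class TestFitSdm:
    def test_glm_recovers_coefficient_signs(self):
        betas = (2.0, -2.0)
        hits = 0
        for seed in range(20):
            pres, back = _logistic_sim(betas=betas, seed=seed)
            res = fit_sdm("GLM", pres, back, seed=seed)
            est = res._state.estimator.coef_[0][:2]  # linear terms
            hits += (np.sign(est) == np.sign(betas)).all()
        assert hits >= 19

    def test_rf_perfect_on_separable_data(self):
        pres = PredictorMatrix(["x"], np.linspace(2, 3, 50)[:, None])
        back = PredictorMatrix(["x"], np.linspace(-3, -2, 50)[:, None])
        res = fit_sdm("RF", pres, back, seed=0)
        scores_p = res.predict(pres.rows)
        scores_b = res.predict(back.rows)
        assert auc(scores_p, scores_b) == 1.0

    @pytest.mark.parametrize("method", METHODS)
    def test_outlier_presence_scores_above_background(self, method):
        # a presence environment far from all background should look better
        # to the model than the average background cell
        rng = np.random.default_rng(1)
        pres_rows = rng.normal(loc=4.0, scale=0.3, size=(30, 2))
        back_rows = rng.normal(loc=0.0, size=(400, 2))
        pres = PredictorMatrix(["a", "b"], pres_rows)
        back = PredictorMatrix(["a", "b"], back_rows)
        res = fit_sdm(method, pres, back, seed=0)
        at_pres = res.predict(np.array([[4.0, 4.0]]))[0]
        assert at_pres > res.predict(back_rows).mean()

    @pytest.mark.parametrize("method", METHODS)
    def test_predictions_in_unit_interval_and_deterministic(self, method):
        pres, back = _logistic_sim(n_pres=60, n_back=300, betas=(1.5, 0.5),
                                   seed=2)
        res1 = fit_sdm(method, pres, back, seed=5)
        res2 = fit_sdm(method, pres, back, seed=5)
        X = np.random.default_rng(0).normal(size=(50, 2)) * 3
        p1, p2 = res1.predict(X), res2.predict(X)
        assert np.array_equal(p1, p2)
        assert np.all((p1 >= 0) & (p1 <= 1))

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        pres = PredictorMatrix(["a", "c"], np.column_stack(
            [rng.normal(size=40) + 2, np.full(40, 7.0)]))
        back = PredictorMatrix(["a", "c"], np.column_stack(
            [rng.normal(size=200), np.full(200, 7.0)]))
        with pytest.warns(UserWarning, match="constant"):
            res = fit_sdm("GLM", pres, back, seed=0)
        assert res.feature_names == ["a"]

    @pytest.mark.parametrize("method", ["GLM", "RF"])
    def test_fitted_model_roundtrips_through_file(self, tmp_path, method):
        pres, back = _logistic_sim(n_pres=60, n_back=300, betas=(1.5, 0.5),
                                   seed=4)
        res = fit_sdm(method, pres, back, seed=1)
        res.save(tmp_path / "model.pkl")
        loaded = SDMResults.load(tmp_path / "model.pkl")
        X = np.random.default_rng(2).normal(size=(40, 2))
        assert np.array_equal(loaded.predict(X), res.predict(X))
        assert loaded.method == method
        assert loaded.training_meta.n_presence == 60

    def test_unknown_method_rejected(self):
        pres, back = _logistic_sim(n_pres=20, n_back=20, betas=(1.0,), seed=0)
        with pytest.raises(ValueError, match="unknown method"):
            SDM("LDA", pres, back)


class TestPredictSurface:
    def test_surface_matches_point_predictions(self):
        stack = _toy_stack()
        rng = np.random.default_rng(4)
        pres = PredictorMatrix(["a", "b"], rng.normal(size=(30, 2)) + 1)
        back = PredictorMatrix(["a", "b"], rng.normal(size=(200, 2)))
        res = fit_sdm("GLM", pres, back, seed=0)
        surf = res.predict_surface(stack)
        r, c = 3, 7
        row = np.array([[stack.grids["a"][r, c], stack.grids["b"][r, c]]])
        assert surf.grid[r, c] == pytest.approx(res.predict(row)[0])

    def test_masked_cells_stay_masked(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5, :] = True
        stack = _toy_stack(mask=mask)
        rng = np.random.default_rng(5)
        pres = PredictorMatrix(["a", "b"], rng.normal(size=(30, 2)) + 1)
        back = PredictorMatrix(["a", "b"], rng.normal(size=(200, 2)))
        surf = fit_sdm("RF", pres, back, seed=0).predict_surface(stack)
        assert np.all(np.isnan(surf.grid[5, :]))

    def test_zero_coefficient_glm_gives_constant_surface(self):
        from scipy.special import expit
        from sklearn.linear_model import LogisticRegression
        from snakerisk.sdm import _TrainingMeta, _quadratic_features

        rng = np.random.default_rng(6)
        X = rng.normal(size=(100, 2))
        y = np.r_[np.ones(50), np.zeros(50)]
        std = _Standardizer(X)
        est = LogisticRegression(C=np.inf).fit(_quadratic_features(std(X)), y)
        est.coef_[:] = 0.0
        est.intercept_[:] = 0.3
        res = SDMResults("GLM", ["a", "b"],
                         _SklearnState(est, std, _quadratic_features),
                         _TrainingMeta(50, 50, 0))
        surf = res.predict_surface(_toy_stack())
        assert np.allclose(surf.grid, expit(0.3))

    def test_missing_layer_named_in_error(self):
        stack = _toy_stack()
        rng = np.random.default_rng(7)
        pres = PredictorMatrix(["a", "z"], rng.normal(size=(30, 2)) + 1)
        back = PredictorMatrix(["a", "z"], rng.normal(size=(200, 2)))
        res = fit_sdm("GLM", pres, back, seed=0)
        with pytest.raises(ValueError, match="z"):
            res.predict_surface(stack)
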