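"""AUC, TSS, maxSSS, Boyce index, permutation importance, evaluate_model."""

import numpy as np
import pytest

from snakerisk import (auc, boyce_index, evaluate_model, max_sss_threshold,
                       tss_at_threshold, variable_importance)
from snakerisk.evaluation import evaluate_scores
from snakerisk.predictors import PredictorMatrix
from snakerisk.sdm import fit_sdm, split_train_test


def auc_pair_oracle(p, b):
    """Exhaustive ordered-pair count; ties one half."""
    p, b = np.asarray(p), np.asarray(b)
    wins = (p[:, None] > b[None, :]).sum() + 0.5 * (p[:, None] == b[None, :]).sum()
    return wins / (len(p) * len(b))


def max_sss_oracle(p, b):
    """Scan every candidate threshold exhaustively."""
    values = np.unique(np.concatenate([p, b]))
    if len(values) == 1:
        t = float(values[0])
        return t, tss_at_threshold(p, b, t)
    span = values[-1] - values[0]
    cands = np.concatenate([[values[0] - 0.5 * span],
                            (values[:-1] + values[1:]) / 2,
                            [values[-1] + 0.5 * span]])
    pairs = [(float(t), tss_at_threshold(p, b, float(t))) for t in cands]
    best = max(v for _, v in pairs)
    t_best = min(t for t, v in pairs if v >= best - 1e-12)
    return t_best, dict(pairs)[t_best]


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.8, 0.9], [0.1, 0.2]) == 1.0

    def test_worked_example(self):
        assert auc([0.9, 0.7], [0.8, 0.1]) == pytest.approx(0.75)

    def test_matches_pair_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.integers(0, 10, size=rng.integers(1, 20)) / 10
            b = rng.integers(0, 10, size=rng.integers(1, 20)) / 10
            assert auc(p, b) == pytest.approx(auc_pair_oracle(p, b))

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.normal(size=15)
            b = rng.normal(size=25)
            assert auc(p, b) + auc(b, p) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc([], [0.5])


class TestTss:
    def test_perfect_separation_is_one(self):
        assert tss_at_threshold([0.8, 0.9], [0.1, 0.2], 0.5) == 1.0

    def test_threshold_below_everything_is_zero(self):
        assert tss_at_threshold([0.8, 0.9], [0.1, 0.2], -1.0) == pytest.approx(0.0)

    def test_arithmetic(self):
        # sens 0.8, spec 0.7 -> 0.5
        p = [1] * 8 + [0] * 2
        b = [0] * 7 + [1] * 3
        assert tss_at_threshold(p, b, 0.5) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        b = rng.random(50)
        t = 0.4
        f = lambda x: np.exp(3 * np.asarray(x))  # strictly increasing
        assert tss_at_threshold(p, b, t) == pytest.approx(
            tss_at_threshold(f(p), f(b), float(f(t))))


class TestMaxSss:
    def test_separable_reaches_one(self):
        t, tss = max_sss_threshold([0.8, 0.9, 0.95], [0.1, 0.2, 0.3])
        assert tss == 1.0
        assert 0.3 < t < 0.8

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            p = rng.integers(0, 8, size=rng.integers(1, 15)) / 8
            b = rng.integers(0, 8, size=rng.integers(1, 15)) / 8
            t, tss = max_sss_threshold(p, b)
            t_o, tss_o = max_sss_oracle(p, b)
            assert tss == pytest.approx(tss_o)
            assert t == pytest.approx(t_o)

    def test_identical_scores_degenerate(self):
        t, tss = max_sss_threshold([0.5, 0.5], [0.5, 0.5])
        assert t == 0.5
        assert tss == 0.0


class TestBoyce:
    def test_monotone_concentration_reaches_plus_one(self):
        xs = np.linspace(0.00025, 0.99975, 2000)
        counts = np.round(1 + 2000 * xs ** 3).astype(int)
        presence = np.repeat(xs, counts)
        landscape = np.linspace(0, 1, 10001)
        assert boyce_index(presence, landscape) == pytest.approx(1.0, abs=1e-12)

    def test_mirrored_concentration_reaches_minus_one(self):
        xs = np.linspace(0.00025, 0.99975, 2000)
        counts = np.round(1 + 2000 * xs ** 3).astype(int)
        presence = 1 - np.repeat(xs, counts)
        landscape = np.linspace(0, 1, 10001)
        assert boyce_index(presence, landscape) == pytest.approx(-1.0, abs=1e-12)

    def test_random_subsample_near_zero(self):
        rng = np.random.default_rng(4)
        vals = []
        for _ in range(200):
            land = rng.random(2000)
            pres = rng.choice(land, size=200, replace=False)
            vals.append(boyce_index(pres, land))
        assert abs(np.mean(vals)) < 0.1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        land = rng.random(3000)
        pres = rng.choice(land, size=300, p=land / land.sum())
        # rank-preserving but non-linear map applied to all predictions;
        # windows are equal-rank-width after mapping only if the map is
        # affine, so invariance is asserted on sign and rough magnitude
        b1 = boyce_index(pres, land)
        b2 = boyce_index(2 * pres + 1, 2 * land + 1)  # affine: exact
        assert b2 == pytest.approx(b1)

    def test_constant_landscape_rejected(self):
        with pytest.raises(ValueError):
            boyce_index([0.5], np.full(100, 0.3))


class TestVariableImportance:
    def _fitted_glm(self, betas, seed=0, n=400):
        rng = np.random.default_rng(seed)
        k = len(betas)
        pool = rng.normal(size=(20 * n, k))
        p = 1 / (1 + np.exp(-(pool @ np.asarray(betas))))
        keep = rng.random(len(p)) < p
        names = [f"x{i}" for i in range(k)]
        pres = PredictorMatrix(names, pool[keep][:n])
        back = PredictorMatrix(names, rng.normal(size=(n, k)))
        return fit_sdm("GLM", pres, back, seed=seed), pres, back

    def test_strong_single_driver_ranks_first(self):
        hits = 0
        for seed in range(10):
            model, pres, back = self._fitted_glm((3.0, 0.1), seed=seed)
            matrix = PredictorMatrix(model.feature_names,
                                     np.vstack([pres.rows, back.rows]))
            table = variable_importance(model, matrix, seed=seed)
            hits += table.top_variable() == "x0"
        assert hits == 10

    def test_importances_within_unit_interval(self):
        model, pres, back = self._fitted_glm((1.0, -1.0), seed=3)
        matrix = PredictorMatrix(model.feature_names,
                                 np.vstack([pres.rows, back.rows]))
        table = variable_importance(model, matrix, seed=0)
        assert all(0 <= v <= 1 for v in table.mean.values())

    def test_ignored_variable_scores_zero(self):
        # a model that never looks at x1: importance of x1 is exactly 0
        class OneVarModel:
            feature_names = ["x0", "x1"]
            method = "toy"

            def predict(self, X):
                return 1 / (1 + np.exp(-X[:, 0]))

        rng = np.random.default_rng(6)
        matrix = PredictorMatrix(["x0", "x1"], rng.normal(size=(200, 2)))
        table = variable_importance(OneVarModel(), matrix, seed=0)
        assert table.mean["x1"] == 0.0
        assert table.mean["x0"] > 0.3


class TestEvaluateModel:
    def test_truth_model_scores_high(self):
        # the true suitability itself, wrapped as a model; its AUC ceiling
        # is bounded by 1 - prevalence/2 because presences are sampled in
        # proportion to suitability, so "high" means clearly above that
        # bound's practical floor, not arbitrarily close to 1
        from snakerisk import define_virtual_species, generate_landscape
        from tests.conftest import RECOVERY_COEFFICIENTS, RECOVERY_INTERCEPT

        stack = generate_landscape(120, 120, seed=31)
        species = define_virtual_species(stack, RECOVERY_COEFFICIENTS,
                                         RECOVERY_INTERCEPT, "sp_truth")
        b = species.coefficients
        a = species.intercept

        class TruthModel:
            feature_names = list(b)
            method = "truth"

            def predict(inner, X):
                eta = a + X @ np.asarray(list(b.values()))
                return 1 / (1 + np.exp(-eta))

        from snakerisk import extract_at_points, sample_background, sample_presences
        # the held-out 20% must be dense enough for a stable Boyce curve
        occ = sample_presences(species, 5000, seed=0,
                               transform=stack.transform)
        sub = stack.subset(list(b))
        pres = extract_at_points(sub, occ)
        bg = sample_background(sub, n=3000, seed=1)
        back = extract_at_points(sub, bg.points, provenance="background")
        split = split_train_test(pres.n, back.n, seed=2)
        cells, values = sub.table()
        land = PredictorMatrix(list(b), values, "cells")
        report = evaluate_model(TruthModel(), split, pres, back,
                                landscape_matrix=land)
        assert report.auc > 0.8
        assert report.boyce > 0.9

    def test_constant_model_is_random(self):
        report = evaluate_scores(np.full(50, 0.4), np.full(500, 0.4))
        assert report.auc == 0.5
        assert report.tss_max == 0.0

    def test_report_fields_within_ranges(self):
        rng = np.random.default_rng(8)
        report = evaluate_scores(rng.random(40), rng.random(400))
        assert 0 <= report.auc <= 1
        assert -1 <= report.tss_max <= 1
        assert -1 <= report.boyce <= 1
        assert report.n_test_presence == 40
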