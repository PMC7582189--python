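"""Presence/background suitability models and their ensemble.

Five base learners are fitted behind one contract — every method maps a row
of predictor values to a suitability score in [0, 1], deterministically for
a fixed seed:

``GLM``
    logistic regression with linear + quadratic terms,
``GAM``
    spline-based logistic additive model (penalized B-splines),
``GBM``
    gradient-boosted classification trees,
``RF``
    random forest (probability votes),
``MAXENT``
    the penalized-logistic-regression equivalent of maximum entropy
    modelling: an L1-regularized logistic model on linear, quadratic and
    hinge features of presence vs background, with the regularization
    strength chosen by internal cross-validation.

For GLM, GAM and MAXENT the background is down-weighted so its total weight
equals the total presence weight; this keeps fitted intercepts from being
dominated by the 100:1 background prevalence.

The user-facing entry point follows the model/results idiom: build an
:class:`EnsembleSDM` from presence and background design matrices, call
``fit()`` and work with the returned :class:`EnsembleSDMResults` (per-method
fits, held-out evaluation, permutation importances, ``summary()``).
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .evaluation import (EvaluationReport, ImportanceTable, evaluate_scores,
                         variable_importance)
from .predictors import PredictorMatrix, extract_at_points
from .raster import EnvStack, SuitabilitySurface

logger = logging.getLogger(__name__)

METHODS = ("GLM", "GAM", "GBM", "RF", "MAXENT")

DEFAULT_N_BACKGROUND = 10_000
DEFAULT_TRAIN_FRACTION = 0.8

#: Per-method hyperparameter defaults; all overridable through the
#: ``hyperparams`` argument of ``fit_sdm`` / ``EnsembleSDM``.
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "GLM": {},
    "GAM": {"df": 4, "degree": 3},
    "GBM": {"n_estimators": 500, "learning_rate": 0.05, "max_depth": 3},
    # depth-limited, class-balanced forest: with ~10^2 presences against
    # 10^4 background points, fully grown trees memorize presence cells and
    # the prevalence swamps the vote; both hurt held-out discrimination
    "RF": {"n_estimators": 500, "max_depth": 6,
           "class_weight": "balanced_subsample"},
    # C grid spans from a fully sparse model to a nearly saturated one
    # (~30 of 35 features active); with presence-matched weights the
    # effective sample is small, so weaker penalties than C~3 only add
    # solver cost without changing the selected model
    "MAXENT": {"n_hinge_knots": 3, "cv_folds": 5,
               "Cs": (0.01, 0.03, 0.1, 0.3, 1.0, 3.0)},
}


@dataclass
class BackgroundSample:
    """Pseudo-absence points drawn from the study extent."""

    points: list[tuple[float, float]]
    n: int
    seed: int

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class TrainTestSplit:
    """Stratified calibration/evaluation split of presence and background."""

    train_presence_idx: np.ndarray
    test_presence_idx: np.ndarray
    train_background_idx: np.ndarray
    test_background_idx: np.ndarray
    fraction: float


def sample_background(stack: EnvStack, n: int = DEFAULT_N_BACKGROUND,
                      seed: int = 0) -> BackgroundSample:
    """Draw n background points uniformly over the non-nodata extent.

    Sampling is without replacement over cells when n does not exceed the
    number of valid cells, otherwise with replacement (with a warning).
    Points sit at cell centres.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = stack.valid_cells()
    if valid.shape[0] == 0:
        raise ValueError("stack has no valid cells to sample background from")
    rng = np.random.default_rng(seed)
    replace = n > valid.shape[0]
    if replace:
        warnings.warn(f"requested {n} background points from {valid.shape[0]} "
                      "valid cells; sampling with replacement", stacklevel=2)
    pick = rng.choice(valid.shape[0], size=n, replace=replace)
    points = [stack.transform.cell_center(r, c) for r, c in valid[pick]]
    return BackgroundSample(points=points, n=n, seed=seed)


def split_train_test(n_presence: int, n_background: int,
                     fraction: float = DEFAULT_TRAIN_FRACTION,
                     seed: int = 0) -> TrainTestSplit:
    """Stratified random split: presences and background split independently
    at the same fraction."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if n_presence < 5:
        raise ValueError("need at least 5 presence records to split; collect "
                         "more occurrences or lower the evaluation demand")
    rng = np.random.default_rng(seed)

    def _split(n: int) -> tuple[np.ndarray, np.ndarray]:
        perm = rng.permutation(n)
        k = int(round(fraction * n))
        k = min(max(k, 1), n - 1)  # both partitions non-empty
        return np.sort(perm[:k]), np.sort(perm[k:])

    tr_p, te_p = _split(n_presence)
    tr_b, te_b = _split(n_background)
    return TrainTestSplit(tr_p, te_p, tr_b, te_b, fraction)


# ---------------------------------------------------------------------------
# feature maps shared by the regression-type learners


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        self.sd = sd

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


def _quadratic_features(X: np.ndarray) -> np.ndarray:
    return np.column_stack([X, X ** 2])


class _HingeFeatures:
    """Linear + quadratic + hinge basis used by the MAXENT learner."""

    def __init__(self, X: np.ndarray, n_knots: int):
        qs = np.linspace(0, 100, n_knots + 2)[1:-1]
        self.knots = np.percentile(X, qs, axis=0)  # (n_knots, n_features)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        parts = [X, X ** 2]
        for k in range(self.knots.shape[0]):
            parts.append(np.maximum(X - self.knots[k], 0.0))
        return np.column_stack(parts)


# ---------------------------------------------------------------------------
# fitted-state wrappers (one per method family)


class _SklearnState:
    def __init__(self, estimator, standardizer, feature_map):
        self.estimator = estimator
        self.standardizer = standardizer
        self.feature_map = feature_map

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = X if self.standardizer is None else self.standardizer(X)
        if self.feature_map is not None:
            Z = self.feature_map(Z)
        return self.estimator.predict_proba(Z)[:, 1]


class _GamState:
    """Fitted GAM: either a statsmodels GLMGam result or the ridge-logistic
    fallback estimator, plus the spline basis and input clamps."""

    def __init__(self, gam_result, fallback_est, smoother, standardizer,
                 clip_lo, clip_hi):
        self.gam_result = gam_result
        self.fallback_est = fallback_est
        self.smoother = smoother
        self.standardizer = standardizer
        self.clip_lo = clip_lo
        self.clip_hi = clip_hi

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = self.standardizer(X)
        # clamped extrapolation: spline bases are undefined beyond the
        # training range, so clip prediction inputs to it
        Z = np.clip(Z, self.clip_lo, self.clip_hi)
        if self.gam_result is not None:
            return np.asarray(self.gam_result.predict(
                exog=np.ones((len(Z), 1)), exog_smooth=Z))
        basis = self.smoother.transform(Z)
        return self.fallback_est.predict_proba(basis)[:, 1]


def _fit_glm(X, y, w, seed, hp):
    from sklearn.linear_model import LogisticRegression

    std = _Standardizer(X)
    Z = _quadratic_features(std(X))
    est = LogisticRegression(C=np.inf, max_iter=5000)  # unpenalized
    est.fit(Z, y, sample_weight=w)
    return _SklearnState(est, std, _quadratic_features)


def _fit_gam(X, y, w, seed, hp):
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    std = _Standardizer(X)
    Z = std(X)
    k = Z.shape[1]
    df = max(int(hp.get("df", 4)), int(hp.get("degree", 3)) + 1)
    bs = BSplines(Z, df=[df] * k, degree=[int(hp.get("degree", 3))] * k)
    result, fallback = None, None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = GLMGam(y, exog=np.ones((len(y), 1)), smoother=bs,
                           family=sm.families.Binomial(), var_weights=w)
            result = model.fit()
    except Exception:
        # perfectly separable (or otherwise degenerate) training data: the
        # unpenalized IRLS diverges; fall back to a ridge-stabilized
        # logistic fit on the same spline basis
        from sklearn.linear_model import LogisticRegression

        fallback = LogisticRegression(C=1e4, max_iter=5000)
        fallback.fit(bs.transform(Z), y, sample_weight=w)
    return _GamState(result, fallback, bs, std, Z.min(axis=0), Z.max(axis=0))


def _fit_gbm(X, y, w, seed, hp):
    from sklearn.ensemble import GradientBoostingClassifier

    est = GradientBoostingClassifier(
        n_estimators=int(hp.get("n_estimators", 500)),
        learning_rate=float(hp.get("learning_rate", 0.05)),
        max_depth=int(hp.get("max_depth", 3)),
        random_state=seed)
    est.fit(X, y)
    return _SklearnState(est, None, None)


def _fit_rf(X, y, w, seed, hp):
    from sklearn.ensemble import RandomForestClassifier

    est = RandomForestClassifier(n_estimators=int(hp.get("n_estimators", 500)),
                                 max_depth=hp.get("max_depth", 6),
                                 class_weight=hp.get("class_weight",
                                                     "balanced_subsample"),
                                 random_state=seed, n_jobs=1)
    est.fit(X, y)
    return _SklearnState(est, None, None)


def _fit_maxent(X, y, w, seed, hp):
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    std = _Standardizer(X)
    fmap = _HingeFeatures(std(X), int(hp.get("n_hinge_knots", 3)))
    Z = fmap(std(X))
    cv = StratifiedKFold(n_splits=int(hp.get("cv_folds", 5)), shuffle=True,
                         random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = LogisticRegressionCV(
            Cs=list(hp.get("Cs", (0.01, 0.03, 0.1, 0.3, 1.0, 3.0))),
            cv=cv, penalty="l1", solver="liblinear",
            max_iter=2000, random_state=seed)
        est.fit(Z, y, sample_weight=w)
    return _SklearnState(est, std, fmap)


_FITTERS = {"GLM": _fit_glm, "GAM": _fit_gam, "GBM": _fit_gbm, "RF": _fit_rf,
            "MAXENT": _fit_maxent}

#: Methods whose background is reweighted to match total presence weight.
_WEIGHTED_METHODS = {"GLM", "GAM", "MAXENT"}


# ---------------------------------------------------------------------------
# model / results objects


@dataclass
class _TrainingMeta:
    n_presence: int
    n_background: int
    seed: int


class SDMResults:
    """A fitted presence/background suitability model.

    Carries the opaque fitted state, the feature names it expects, and
    training metadata; ``predict`` returns suitability scores in [0, 1] and
    ``predict_surface`` evaluates the model over a whole environment stack.
    """

    def __init__(self, method: str, feature_names: list[str], state,
                 training_meta: _TrainingMeta):
        self.method = method
        self.feature_names = list(feature_names)
        self._state = state
        self.training_meta = training_meta

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError(f"expected {len(self.feature_names)} features "
                             f"({self.feature_names}), got {X.shape[1]}")
        p = np.asarray(self._state.predict(X), dtype=float)
        return np.clip(p, 0.0, 1.0)

    def predict_matrix(self, matrix: PredictorMatrix) -> np.ndarray:
        if list(matrix.column_names) != self.feature_names:
            matrix = matrix.subset(self.feature_names)
        return self.predict(matrix.rows)

    def save(self, path) -> None:
        """Serialize the fitted state (pickle with a format-version tag)."""
        import pickle
        from pathlib import Path

        from . import __version__

        payload = {"format_version": 1, "package_version": __version__,
                   "method": self.method, "feature_names": self.feature_names,
                   "state": self._state, "training_meta": self.training_meta}
        Path(path).write_bytes(pickle.dumps(payload))

    @classmethod
    def load(cls, path) -> "SDMResults":
        import pickle
        from pathlib import Path

        payload = pickle.loads(Path(path).read_bytes())
        if payload.get("format_version") != 1:
            raise ValueError(f"unsupported model file version in {path}")
        return cls(payload["method"], payload["feature_names"],
                   payload["state"], payload["training_meta"])

    def predict_surface(self, stack: EnvStack, species_id: str = "species"
                        ) -> SuitabilitySurface:
        missing = [n for n in self.feature_names if n not in stack.layer_names]
        if missing:
            raise ValueError(f"stack is missing required layers: {missing}")
        sub = stack.subset(self.feature_names)
        cells, values = sub.table()
        preds = self.predict(values)
        grid = np.full(stack.shape, np.nan)
        grid[cells[:, 0], cells[:, 1]] = preds
        return SuitabilitySurface(grid=grid, nodata_mask=stack.nodata_mask,
                                  species_id=species_id, method=self.method,
                                  transform=stack.transform)


class SDM:
    """One presence/background suitability model, before fitting.

    Parameters
    ----------
    method
        One of ``GLM, GAM, GBM, RF, MAXENT``.
    presence_matrix, background_matrix
        PredictorMatrix objects sharing identical columns.
    hyperparams
        Overrides merged onto the method's defaults.
    """

    def __init__(self, method: str, presence_matrix: PredictorMatrix,
                 background_matrix: PredictorMatrix,
                 hyperparams: dict | None = None):
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
        if list(presence_matrix.column_names) != list(background_matrix.column_names):
            raise ValueError("presence and background matrices must share columns")
        self.method = method
        self.presence = presence_matrix
        self.background = background_matrix
        self.hyperparams = {**DEFAULT_HYPERPARAMS[method], **(hyperparams or {})}

    def fit(self, seed: int = 0, presence_idx: np.ndarray | None = None,
            background_idx: np.ndarray | None = None) -> SDMResults:
        """Fit on the given row subsets (defaults: all rows)."""
        Xp = self.presence.rows if presence_idx is None else self.presence.rows[presence_idx]
        Xb = self.background.rows if background_idx is None else self.background.rows[background_idx]
        if len(Xp) == 0 or len(Xb) == 0:
            raise ValueError("both presence and background training rows are required")
        names = list(self.presence.column_names)
        X = np.vstack([Xp, Xb])

        keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
        if len(keep) < X.shape[1]:
            dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
            warnings.warn(f"dropping constant predictor column(s): {dropped}",
                          stacklevel=2)
            if not keep:
                raise ValueError("all predictor columns are constant")
            X = X[:, keep]
            names = [names[j] for j in keep]

        y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xb))])
        if self.method in _WEIGHTED_METHODS:
            w = np.concatenate([np.ones(len(Xp)),
                                np.full(len(Xb), len(Xp) / len(Xb))])
        else:
            w = np.ones(len(y))
        state = _FITTERS[self.method](X, y, w, seed, self.hyperparams)
        meta = _TrainingMeta(n_presence=len(Xp), n_background=len(Xb), seed=seed)
        return SDMResults(self.method, names, state, meta)


def fit_sdm(method: str, presence_matrix: PredictorMatrix,
            background_matrix: PredictorMatrix,
            hyperparams: dict | None = None, seed: int = 0) -> SDMResults:
    """Functional one-shot: construct an SDM and fit it on all rows."""
    return SDM(method, presence_matrix, background_matrix, hyperparams).fit(seed)


def predict_surface(model: SDMResults, stack: EnvStack,
                    species_id: str = "species") -> SuitabilitySurface:
    """Evaluate a fitted model cellwise over an environment stack."""
    return model.predict_surface(stack, species_id=species_id)


class _MeanPredictor:
    """Equal-weight mean of several fitted models; used for ensemble
    prediction and ensemble-level permutation importance."""

    def __init__(self, models: dict[str, SDMResults], weights=None):
        self.models = models
        self.feature_names = next(iter(models.values())).feature_names
        self.method = "ensemble"
        if weights is None:
            weights = {m: 1.0 for m in models}
        total = sum(weights.values())
        self.weights = {m: weights[m] / total for m in models}

    def predict(self, X: np.ndarray) -> np.ndarray:
        return sum(self.weights[m] * r.predict(X) for m, r in self.models.items())


class EnsembleSDMResults:
    """Fit results for one species: five base models, their held-out
    evaluations, the ensemble evaluation, and permutation importances."""

    def __init__(self, species_id: str, models: dict[str, SDMResults],
                 evaluations: dict[str, EvaluationReport],
                 importance: ImportanceTable, split: TrainTestSplit,
                 feature_names: list[str]):
        self.species_id = species_id
        self.models = models
        self.evaluations = evaluations
        self.importance = importance
        self.split = split
        self.feature_names = list(feature_names)

    def predict(self, X: np.ndarray, weighting: str = "equal") -> np.ndarray:
        return self._mean_predictor(weighting).predict(np.atleast_2d(X))

    def _mean_predictor(self, weighting: str = "equal") -> _MeanPredictor:
        if weighting == "equal":
            return _MeanPredictor(self.models)
        if weighting == "tss":
            w = {m: max(self.evaluations[m].tss_max, 1e-6) for m in self.models}
            return _MeanPredictor(self.models, weights=w)
        raise ValueError("weighting must be 'equal' or 'tss'")

    def method_surfaces(self, stack: EnvStack) -> dict[str, SuitabilitySurface]:
        return {m: r.predict_surface(stack, species_id=self.species_id)
                for m, r in self.models.items()}

    def ensemble_surface(self, stack: EnvStack, weighting: str = "equal"
                         ) -> SuitabilitySurface:
        pred = self._mean_predictor(weighting)
        sub = stack.subset(self.feature_names)
        cells, values = sub.table()
        grid = np.full(stack.shape, np.nan)
        grid[cells[:, 0], cells[:, 1]] = pred.predict(values)
        return SuitabilitySurface(grid=grid, nodata_mask=stack.nodata_mask,
                                  species_id=self.species_id, method="ensemble",
                                  transform=stack.transform)

    def summary(self) -> str:
        lines = [
            f"Ensemble SDM results — species: {self.species_id}",
            f"presence: {len(self.split.train_presence_idx)} train / "
            f"{len(self.split.test_presence_idx)} test;  background: "
            f"{len(self.split.train_background_idx)} train / "
            f"{len(self.split.test_background_idx)} test",
            "",
            f"{'method':>8} {'AUC':>7} {'maxTSS':>7} {'Boyce':>7} {'maxSSS thr':>11}",
        ]
        order = list(self.models) + ["ensemble"]
        for m in order:
            e = self.evaluations[m]
            lines.append(f"{m:>8} {e.auc:7.3f} {e.tss_max:7.3f} {e.boyce:7.3f} "
                         f"{e.max_sss_threshold:11.3f}")
        lines.append("")
        lines.append("permutation importance (ensemble):")
        for v in self.importance.ranked():
            lines.append(f"  {v:>10}: {self.importance.mean[v]:.3f} "
                         f"(sd {self.importance.sd[v]:.3f})")
        return "\n".join(lines)


class EnsembleSDM:
    """Ensemble suitability model for one species.

    Build from presence and background design matrices (or from points via
    :meth:`from_points`), then ``fit(seed)``.  Fitting draws an 80/20
    stratified calibration split, trains each base method on the
    calibration portion, evaluates every method and the equal-weight
    ensemble on the held-out portion, and computes ensemble-level
    permutation variable importances.
    """

    def __init__(self, presence_matrix: PredictorMatrix,
                 background_matrix: PredictorMatrix,
                 species_id: str = "species",
                 methods: tuple[str, ...] = METHODS,
                 hyperparams: dict[str, dict] | None = None,
                 train_fraction: float = DEFAULT_TRAIN_FRACTION,
                 n_permutations: int = 10,
                 n_importance_rows: int = 500):
        unknown = [m for m in methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown methods: {unknown}")
        self.presence = presence_matrix
        self.background = background_matrix
        self.species_id = species_id
        self.methods = tuple(methods)
        self.hyperparams = copy.deepcopy(hyperparams or {})
        self.train_fraction = train_fraction
        self.n_permutations = n_permutations
        self.n_importance_rows = n_importance_rows

    @classmethod
    def from_points(cls, stack: EnvStack, occurrences, species_id: str | None = None,
                    n_background: int = DEFAULT_N_BACKGROUND, seed: int = 0,
                    layers: list[str] | None = None, **kwargs) -> "EnsembleSDM":
        """Assemble the design matrices from occurrence points and a fresh
        background sample over the stack (optionally restricted to
        VIF-retained layers)."""
        use = stack if layers is None else stack.subset(layers)
        presence = extract_at_points(use, occurrences, provenance="occurrences")
        bg = sample_background(use, n=n_background, seed=seed)
        background = extract_at_points(use, bg.points, provenance="background")
        sid = species_id or getattr(occurrences, "species_id", "species")
        return cls(presence, background, species_id=sid, **kwargs)

    def fit(self, seed: int = 0) -> EnsembleSDMResults:
        split = split_train_test(self.presence.n, self.background.n,
                                 fraction=self.train_fraction, seed=seed)
        models: dict[str, SDMResults] = {}
        evaluations: dict[str, EvaluationReport] = {}
        for i, method in enumerate(self.methods):
            sdm = SDM(method, self.presence, self.background,
                      self.hyperparams.get(method))
            models[method] = sdm.fit(seed=seed + i,
                                     presence_idx=split.train_presence_idx,
                                     background_idx=split.train_background_idx)
        feature_names = next(iter(models.values())).feature_names
        pres = self.presence.subset(feature_names)
        back = self.background.subset(feature_names)
        te_p, te_b = split.test_presence_idx, split.test_background_idx
        test_scores: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for method, res in models.items():
            sp = res.predict(pres.rows[te_p])
            sb = res.predict(back.rows[te_b])
            test_scores[method] = (sp, sb)
            evaluations[method] = evaluate_scores(sp, sb, species_id=self.species_id,
                                                  method=method)
        ens_p = np.mean([test_scores[m][0] for m in models], axis=0)
        ens_b = np.mean([test_scores[m][1] for m in models], axis=0)
        evaluations["ensemble"] = evaluate_scores(ens_p, ens_b,
                                                  species_id=self.species_id,
                                                  method="ensemble")
        mean_pred = _MeanPredictor(models)
        imp_matrix = self._importance_matrix(pres, back, seed)
        importance = variable_importance(mean_pred, imp_matrix,
                                         n_permutations=self.n_permutations,
                                         seed=seed)
        importance.species_id = self.species_id
        importance.method = "ensemble"
        return EnsembleSDMResults(self.species_id, models, evaluations,
                                  importance, split, feature_names)

    def _importance_matrix(self, pres: PredictorMatrix, back: PredictorMatrix,
                           seed: int) -> PredictorMatrix:
        rows = np.vstack([pres.rows, back.rows])
        if rows.shape[0] > self.n_importance_rows:
            rng = np.random.default_rng(seed)
            pick = rng.choice(rows.shape[0], size=self.n_importance_rows,
                              replace=False)
            rows = rows[pick]
        return PredictorMatrix(list(pres.column_names), rows,
                               provenance="importance-sample")
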