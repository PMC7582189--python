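"""Model-performance metrics for presence/background suitability models.

Implements the three metrics commonly used to judge habitat suitability
models — AUC (rank-based, Mann-Whitney form), the true skill statistic
(TSS = sensitivity + specificity - 1, reported at its maximizing
threshold), and the continuous Boyce index (rank correlation between the
predicted-to-expected presence ratio and suitability across moving
windows) — together with maxSSS thresholding for binarizing continuous
suitability and permutation-based variable importance.

Threshold convention, fixed across all operations here: a presence scoring
*greater than or equal to* the threshold counts as predicted-suitable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_BOYCE_WINDOWS = 101
DEFAULT_BOYCE_WIDTH_FRACTION = 0.1
DEFAULT_N_PERMUTATIONS = 10


@dataclass
class EvaluationReport:
    """Held-out performance of one suitability model."""

    auc: float
    tss_max: float
    tss_threshold: float
    boyce: float
    max_sss_threshold: float
    n_test_presence: int
    n_test_background: int
    species_id: str = ""
    method: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_frame(self) -> pd.DataFrame:
        """Tidy `species,method,metric,value` rows."""
        metrics = {"auc": self.auc, "tss_max": self.tss_max, "boyce": self.boyce,
                   "max_sss_threshold": self.max_sss_threshold}
        return pd.DataFrame([
            {"species": self.species_id, "method": self.method,
             "metric": k, "value": v} for k, v in metrics.items()
        ])


@dataclass
class ImportanceTable:
    """Permutation importances (biomod2-style) for one model."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_permutations: int
    seed: int
    species_id: str = ""
    method: str = ""

    def ranked(self) -> list[str]:
        return sorted(self.mean, key=self.mean.get, reverse=True)

    def top_variable(self) -> str:
        return self.ranked()[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"species": self.species_id, "method": self.method, "variable": v,
             "importance_mean": self.mean[v], "importance_sd": self.sd[v]}
            for v in self.ranked()
        ])

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean, "sd": self.sd,
            "n_permutations": self.n_permutations, "seed": self.seed,
            "species_id": self.species_id, "method": self.method,
        }, indent=2))


def auc(presence_scores, background_scores) -> float:
    """Probability a random presence outscores a random background point.

    Mann-Whitney form; ties count one half.  Equals the area under the ROC
    curve of the presence-vs-background classification.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    # rank-based U statistic: O((n+m) log(n+m)) rather than the n*m pair scan
    combined = np.concatenate([p, b])
    ranks = stats.rankdata(combined)
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def tss_at_threshold(presence_scores, background_scores, threshold: float) -> float:
    """True skill statistic at a fixed threshold.

    Sensitivity counts presences scoring >= threshold; specificity counts
    background scoring < threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    sens = float(np.mean(p >= threshold))
    spec = float(np.mean(b < threshold))
    return sens + spec - 1.0


def max_sss_threshold(presence_scores, background_scores) -> tuple[float, float]:
    """Threshold maximizing sensitivity + specificity, and the TSS there.

    Candidate thresholds are the midpoints between consecutive distinct
    observed scores, plus one candidate below the minimum and one above the
    maximum.  Ties in the objective break toward the lowest threshold.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    values = np.unique(np.concatenate([p, b]))
    if values.size == 1:
        return float(values[0]), tss_at_threshold(p, b, float(values[0]))
    mids = (values[:-1] + values[1:]) / 2.0
    span = values[-1] - values[0]
    candidates = np.concatenate([[values[0] - 0.5 * span], mids,
                                 [values[-1] + 0.5 * span]])
    scores = np.array([tss_at_threshold(p, b, float(t)) for t in candidates])
    best = scores.max()
    # ties (within float tolerance) break toward the lowest threshold
    best_t = float(candidates[np.flatnonzero(scores >= best - 1e-12)[0]])
    return best_t, float(scores[candidates.tolist().index(best_t)])


def boyce_index(presence_predictions, landscape_predictions,
                n_windows: int = DEFAULT_BOYCE_WINDOWS,
                window_width_fraction: float = DEFAULT_BOYCE_WIDTH_FRACTION,
                ) -> float:
    """Continuous Boyce index of presence-only calibration.

    Moving windows of width ``window_width_fraction * (max - min)`` of the
    landscape predictions are slid across that range at ``n_windows`` evenly
    spaced centre positions.  Per window, F = (fraction of presence
    predictions inside) / (fraction of landscape predictions inside);
    windows containing no landscape predictions are dropped.  The index is
    the Spearman rank correlation between F and the window midpoint: +1
    means observed presences concentrate monotonically in the most suitable
    windows, 0 means no better than random.
    """
    p = np.asarray(presence_predictions, dtype=float)
    land = np.asarray(landscape_predictions, dtype=float)
    if p.size == 0 or land.size == 0:
        raise ValueError("prediction lists must be non-empty")
    if not (0 < window_width_fraction < 1):
        raise ValueError("window_width_fraction must be in (0, 1)")
    lo, hi = float(land.min()), float(land.max())
    width = window_width_fraction * (hi - lo)
    if width <= 0:
        raise ValueError("landscape predictions are constant; Boyce undefined")
    centers = np.linspace(lo + width / 2.0, hi - width / 2.0, n_windows)
    f_vals, mids = [], []
    for c in centers:
        lo_w, hi_w = c - width / 2.0, c + width / 2.0
        land_frac = np.mean((land >= lo_w) & (land <= hi_w))
        if land_frac == 0:
            continue
        pres_frac = np.mean((p >= lo_w) & (p <= hi_w))
        f_vals.append(pres_frac / land_frac)
        mids.append(c)
    if len(f_vals) < 3:
        raise ValueError("fewer than 3 usable windows; increase data or width")
    rho = stats.spearmanr(mids, f_vals).statistic
    return float(rho)


def variable_importance(model, matrix, n_permutations: int = DEFAULT_N_PERMUTATIONS,
                        seed: int = 0) -> ImportanceTable:
    """Permutation variable importance, biomod2 convention.

    For each variable: importance = 1 - |Pearson correlation between the
    model's predictions on the original matrix and on the matrix with that
    single column permuted|, averaged over ``n_permutations`` shuffles.
    A variable the model ignores scores 0; a variable whose shuffling
    destroys the prediction ranking scores near 1.

    ``model`` is anything with ``predict(X) -> scores`` and
    ``feature_names``; ``matrix`` is a PredictorMatrix over those features.
    """
    names = list(model.feature_names)
    if list(matrix.column_names) != names:
        matrix = matrix.subset(names)
    X = matrix.rows
    rng = np.random.default_rng(seed)
    base = np.asarray(model.predict(X), dtype=float)
    constant_base = np.std(base) == 0
    if constant_base:
        logger.warning("variable_importance: model predictions are constant; "
                       "all importances set to 0")
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for j, name in enumerate(names):
        vals = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(X.shape[0]), j]
            pred = np.asarray(model.predict(Xp), dtype=float)
            if constant_base or np.std(pred) == 0:
                # a permutation that leaves predictions constant carries no
                # correlation signal; treat as unchanged unless base varies
                vals.append(0.0 if constant_base else 1.0)
                continue
            r = np.corrcoef(base, pred)[0, 1]
            vals.append(1.0 - abs(float(r)))
        vals = np.asarray(vals)
        mean[name] = float(np.clip(vals.mean(), 0.0, 1.0))
        sd[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return ImportanceTable(mean=mean, sd=sd, n_permutations=n_permutations,
                           seed=seed, method=getattr(model, "method", ""))


def evaluate_scores(test_presence_scores, test_background_scores,
                    landscape_predictions=None,
                    species_id: str = "", method: str = "") -> EvaluationReport:
    """Build an EvaluationReport from held-out scores.

    The Boyce reference distribution is ``landscape_predictions`` when
    given (the model evaluated over the whole landscape), otherwise the
    test background scores, which are themselves a random sample of the
    landscape.
    """
    p = np.asarray(test_presence_scores, dtype=float)
    b = np.asarray(test_background_scores, dtype=float)
    land = b if landscape_predictions is None else np.asarray(landscape_predictions)
    a = auc(p, b)
    t, tss_max = max_sss_threshold(p, b)
    try:
        boyce = boyce_index(p, land)
    except ValueError:
        logger.warning("Boyce index undefined on this evaluation set; reporting 0")
        boyce = 0.0
    return EvaluationReport(auc=a, tss_max=tss_max, tss_threshold=t, boyce=boyce,
                            max_sss_threshold=t, n_test_presence=int(p.size),
                            n_test_background=int(b.size),
                            species_id=species_id, method=method)


def evaluate_model(model, split, presence_matrix, background_matrix,
                   landscape_matrix=None, species_id: str = "") -> EvaluationReport:
    """Evaluate a fitted model on the held-out test partition of a split.

    ``model`` needs ``predict(X)`` and ``feature_names``; matrices are
    PredictorMatrix objects over (at least) those features.  When
    ``landscape_matrix`` is given it provides the Boyce reference
    distribution (predictions across the whole landscape).
    """
    names = list(model.feature_names)
    pres = presence_matrix.subset(names) if list(presence_matrix.column_names) != names else presence_matrix
    back = background_matrix.subset(names) if list(background_matrix.column_names) != names else background_matrix
    if len(split.test_presence_idx) == 0 or len(split.test_background_idx) == 0:
        raise ValueError("test partitions must be non-empty")
    p_scores = np.asarray(model.predict(pres.rows[split.test_presence_idx]))
    b_scores = np.asarray(model.predict(back.rows[split.test_background_idx]))
    land = None
    if landscape_matrix is not None:
        lm = landscape_matrix.subset(names) if list(landscape_matrix.column_names) != names else landscape_matrix
        land = np.asarray(model.predict(lm.rows))
    return evaluate_scores(p_scores, b_scores, landscape_predictions=land,
                           species_id=species_id,
                           method=getattr(model, "method", ""))
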