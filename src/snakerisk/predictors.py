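"""Predictor preparation and collinearity screening.

Covers the steps between raw environmental layers and a design matrix fit
for modelling: derivation of topographic heterogeneity from elevation,
extraction of layer values at points, and variance-inflation-factor (VIF)
screening to ensure low collinearity among the retained predictors.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import EnvStack, points_to_cells

logger = logging.getLogger(__name__)

#: Retains any predictor set whose mutual collinearity is modest
#: (VIF < 5 corresponds to R^2 < 0.8 against the other predictors).
DEFAULT_VIF_THRESHOLD = 5.0

#: Cells sampled for stack-level VIF screening; keeps the OLS solves cheap
#: on large grids while leaving the estimate stable.
DEFAULT_VIF_SAMPLE_CELLS = 10_000


@dataclass
class PredictorMatrix:
    """Design matrix of predictor values at sampled points or cells."""

    column_names: list[str]
    rows: np.ndarray
    provenance: str = "cells"
    n_dropped_nodata: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.column_names):
            raise ValueError("rows must be 2D with one column per name")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("PredictorMatrix must not contain missing values")

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.rows[:, self.column_names.index(name)]

    def subset(self, names: list[str]) -> "PredictorMatrix":
        idx = [self.column_names.index(n) for n in names]
        return PredictorMatrix(list(names), self.rows[:, idx], self.provenance,
                               self.n_dropped_nodata)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.column_names)


@dataclass
class VifReport:
    """Outcome of an iterative VIF screen."""

    vif: dict[str, float]
    retained: list[str]
    dropped: list[str]
    threshold: float
    history: list[dict[str, float]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "threshold": self.threshold,
            "vif": self.vif,
            "retained": self.retained,
            "dropped": self.dropped,
        }, indent=2))

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: variable, VIF (final value), retained flag."""
        rows = []
        for name in list(self.vif):
            rows.append({"variable": name, "vif": self.vif[name],
                         "retained": name in self.retained})
        return pd.DataFrame(rows)


def topographic_heterogeneity(elevation: np.ndarray, window: int = 3) -> np.ndarray:
    """Windowed standard deviation of elevation (terrain ruggedness layer).

    Each cell gets the sample (n-1) standard deviation of the elevation
    values in its ``window x window`` neighbourhood; edge cells use the
    truncated window so the output extent equals the input extent.  NaN
    cells (nodata) are excluded from every window and propagate to the
    output where the centre cell is NaN.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    elev = np.asarray(elevation, dtype=float)
    half = window // 2
    padded = np.pad(elev, half, mode="constant", constant_values=np.nan)
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    view = view.reshape(elev.shape[0], elev.shape[1], -1)
    counts = np.sum(~np.isnan(view), axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.nanstd(view, axis=2, ddof=1)
    sd[counts < 2] = 0.0
    sd[np.isnan(elev)] = np.nan
    return sd


def extract_at_points(stack: EnvStack, points, provenance: str = "occurrences"
                      ) -> PredictorMatrix:
    """Extract layer values at the cells containing the given points.

    Points outside the extent or on nodata cells are dropped; the count of
    dropped points is logged and recorded on the returned matrix.
    """
    pts = getattr(points, "points", points)
    pts = list(pts)
    if not pts:
        raise ValueError("points must be non-empty")
    cells, inside = points_to_cells(pts, stack.transform, stack.shape)
    keep = inside.copy()
    rows_idx = cells[:, 0]
    cols_idx = cells[:, 1]
    keep[inside] &= ~stack.nodata_mask[rows_idx[inside], cols_idx[inside]]
    n_dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all points fall outside the extent or on nodata cells")
    if n_dropped:
        logger.info("extract_at_points: dropped %d of %d points (outside extent "
                    "or nodata)", n_dropped, len(pts))
    values = stack.cell_values(rows_idx[keep], cols_idx[keep])
    return PredictorMatrix(list(stack.layer_names), values, provenance,
                           n_dropped_nodata=n_dropped)


def compute_vif(matrix: PredictorMatrix) -> dict[str, float]:
    """Variance inflation factor per column: VIF_j = 1 / (1 - R^2_j).

    R^2_j comes from the OLS regression (with intercept) of column j on all
    other columns.  Exactly collinear columns are reported as ``inf`` rather
    than raising.
    """
    X = matrix.rows
    names = matrix.column_names
    if len(names) < 2:
        raise ValueError("VIF needs at least two columns")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("VIF needs more rows than columns")
    out: dict[str, float] = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        design = np.column_stack([np.ones(len(y)), others])
        beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            out[name] = math.inf  # constant column: undefined, flag as inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_screen(matrix: PredictorMatrix, threshold: float = DEFAULT_VIF_THRESHOLD
               ) -> VifReport:
    """Iteratively drop the highest-VIF variable until all VIF < threshold.

    VIFs are recomputed after each drop.  Screening stops early if fewer
    than two variables remain.
    """
    if threshold <= 1:
        raise ValueError("threshold must be > 1")
    current = list(matrix.column_names)
    dropped: list[str] = []
    history: list[dict[str, float]] = []
    # final VIF per variable: retained values from the last iteration,
    # dropped values as of the iteration that removed them
    final_vif = {name: 1.0 for name in current}
    while len(current) >= 2:
        vif = compute_vif(matrix.subset(current))
        history.append(dict(vif))
        final_vif.update(vif)
        worst = max(current, key=lambda n: vif[n])
        if vif[worst] < threshold:
            break
        current.remove(worst)
        dropped.append(worst)
        logger.info("vif_screen: dropped %r (VIF=%.3g)", worst, vif[worst])
    ordered = {n: final_vif[n] for n in matrix.column_names}
    return VifReport(vif=ordered, retained=current, dropped=dropped,
                     threshold=threshold, history=history)


def screen_stack(stack: EnvStack, threshold: float = DEFAULT_VIF_THRESHOLD,
                 n_sample_cells: int = DEFAULT_VIF_SAMPLE_CELLS,
                 seed: int = 0) -> VifReport:
    """VIF-screen a whole stack on a random sample of non-nodata cells."""
    cells = stack.valid_cells()
    rng = np.random.default_rng(seed)
    if cells.shape[0] > n_sample_cells:
        pick = rng.choice(cells.shape[0], size=n_sample_cells, replace=False)
        cells = cells[pick]
    values = stack.cell_values(cells[:, 0], cells[:, 1])
    matrix = PredictorMatrix(list(stack.layer_names), values, provenance="cells")
    return vif_screen(matrix, threshold)
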