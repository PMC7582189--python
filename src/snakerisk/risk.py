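"""Multi-species risk surfaces and risk classification.

The per-species ensemble suitability surfaces are combined multiplicatively:
risk at a cell is the product of the species' suitabilities there, so risk
is high only where several species find suitable habitat simultaneously.
The continuous surface can then be binarized at a threshold (conventionally
the maxSSS threshold of the contributing model) or classified into
not-at-risk / moderate / high bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .raster import GridTransform, SuitabilitySurface, default_transform


@dataclass
class RiskSurface:
    """Cellwise product of per-species ensemble suitabilities, in [0, 1]."""

    grid: np.ndarray
    nodata_mask: np.ndarray
    contributing_species: list[str]
    transform: GridTransform = field(default_factory=default_transform)

    def values(self) -> np.ndarray:
        return self.grid[~self.nodata_mask]

    def rescaled(self) -> np.ndarray:
        """Min-max rescaled copy of the grid (display convenience only)."""
        vals = self.values()
        lo, hi = float(vals.min()), float(vals.max())
        out = np.array(self.grid, copy=True)
        if hi > lo:
            out[~self.nodata_mask] = (vals - lo) / (hi - lo)
        return out

    def as_surface(self) -> SuitabilitySurface:
        return SuitabilitySurface(grid=self.grid, nodata_mask=self.nodata_mask,
                                  species_id="+".join(self.contributing_species),
                                  method="risk-product", transform=self.transform)

    def save(self, path) -> None:
        from .raster import write_ascii_grid
        write_ascii_grid(path, self.grid, self.transform, self.nodata_mask)


@dataclass
class RiskClassMap:
    """Categorical risk map: 0 = not at risk, 1 = moderate, 2 = high.

    Classes follow closed-upper thresholds: class 0 below ``t_suitable``,
    class 2 at or above ``t_high``, class 1 in between.
    """

    grid: np.ndarray
    thresholds: tuple[float, float]
    nodata_mask: np.ndarray
    transform: GridTransform = field(default_factory=default_transform)

    @property
    def t_suitable(self) -> float:
        return self.thresholds[0]

    @property
    def t_high(self) -> float:
        return self.thresholds[1]

    def save(self, path) -> None:
        from .raster import write_ascii_grid
        out = self.grid.astype(float)
        write_ascii_grid(path, out, self.transform, self.nodata_mask)


def _check_geometry(surfaces: list[SuitabilitySurface]) -> None:
    ref = surfaces[0]
    for s in surfaces[1:]:
        if s.shape != ref.shape:
            raise ValueError("surfaces differ in grid shape")
        if s.transform.as_tuple() != ref.transform.as_tuple():
            raise ValueError("surfaces differ in geotransform")


def ensemble_mean(surfaces: list[SuitabilitySurface],
                  weights: list[float] | None = None) -> SuitabilitySurface:
    """Cellwise weighted mean of suitability surfaces (weights normalized to
    sum 1; default equal)."""
    if not surfaces:
        raise ValueError("need at least one surface")
    _check_geometry(surfaces)
    if weights is None:
        weights = [1.0] * len(surfaces)
    if len(weights) != len(surfaces):
        raise ValueError("one weight per surface required")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    w = w / w.sum()
    grid = sum(wi * s.grid for wi, s in zip(w, surfaces))
    mask = np.zeros(surfaces[0].shape, dtype=bool)
    for s in surfaces:
        mask |= s.nodata_mask
    grid = np.asarray(grid, dtype=float)
    grid[mask] = np.nan
    return SuitabilitySurface(grid=grid, nodata_mask=mask,
                              species_id=surfaces[0].species_id,
                              method="ensemble", transform=surfaces[0].transform)


def risk_product(ensembles: list[SuitabilitySurface]) -> RiskSurface:
    """Multiply per-species suitability surfaces into one risk surface.

    Order-invariant; a cell is nodata if any contributor is nodata.
    """
    if len(ensembles) < 2:
        raise ValueError("risk product needs at least two species surfaces")
    _check_geometry(ensembles)
    mask = np.zeros(ensembles[0].shape, dtype=bool)
    for s in ensembles:
        mask |= s.nodata_mask
    grid = np.ones(ensembles[0].shape, dtype=float)
    for s in ensembles:
        grid = grid * np.nan_to_num(s.grid, nan=1.0)
    grid[mask] = np.nan
    return RiskSurface(grid=grid, nodata_mask=mask,
                       contributing_species=[s.species_id for s in ensembles],
                       transform=ensembles[0].transform)


def binarize(surface: SuitabilitySurface | RiskSurface, threshold: float
             ) -> np.ndarray:
    """Binary suitable/unsuitable grid: suitable where value >= threshold.

    Returns a float grid of {0.0, 1.0} with NaN on nodata cells.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie strictly between 0 and 1")
    grid = np.where(surface.grid >= threshold, 1.0, 0.0)
    grid[surface.nodata_mask] = np.nan
    return grid


def classify_risk(surface: SuitabilitySurface | RiskSurface,
                  t_suitable: float, t_high: float) -> RiskClassMap:
    """Three-class risk map from a continuous surface.

    class 0 (not at risk): value < t_suitable;
    class 1 (moderate):    t_suitable <= value < t_high;
    class 2 (high):        value >= t_high.
    """
    if not (0 < t_suitable < t_high < 1):
        raise ValueError("need 0 < t_suitable < t_high < 1")
    grid = np.zeros(surface.grid.shape, dtype=int)
    with np.errstate(invalid="ignore"):
        grid[surface.grid >= t_suitable] = 1
        grid[surface.grid >= t_high] = 2
    grid[surface.nodata_mask] = -1  # nodata sentinel for categorical grid
    return RiskClassMap(grid=grid, thresholds=(float(t_suitable), float(t_high)),
                        nodata_mask=surface.nodata_mask,
                        transform=surface.transform)


def default_class_thresholds(surface: SuitabilitySurface, max_sss: float
                             ) -> tuple[float, float]:
    """Default moderate/high band edges for a species map.

    ``t_suitable`` is the model's maxSSS threshold; ``t_high`` the midpoint
    between it and the maximum observed suitability.
    """
    vals = surface.values()
    top = float(vals.max())
    t_suitable = float(max_sss)
    t_high = (t_suitable + top) / 2.0
    if not t_suitable < t_high:
        t_high = min(0.999999, t_suitable + 1e-6)
    return t_suitable, t_high
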