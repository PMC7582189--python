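"""Settlement exposure tabulation and suitable-area computation.

Given a categorical risk map per species and the settlement points of the
study region, count the settlements falling in moderate- and high-risk
cells and measure the suitable area.  Under the synthetic equal-area CRS
every cell has the same area; for geographic (lon/lat) grids the per-row
cell area is scaled by the cosine of the row-centre latitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import points_to_cells
from .risk import RiskClassMap
from .synthetic import VillagePoints

logger = logging.getLogger(__name__)


@dataclass
class ExposureRow:
    species: str
    villages_high: int
    villages_moderate: int
    area_suitable_km2: float


@dataclass
class ExposureTable:
    """Per-species settlement counts and suitable area."""

    rows: list[ExposureRow] = field(default_factory=list)

    def add(self, species: str, villages_high: int, villages_moderate: int,
            area_suitable_km2: float) -> None:
        if villages_high < 0 or villages_moderate < 0 or area_suitable_km2 < 0:
            raise ValueError("exposure entries must be non-negative")
        self.rows.append(ExposureRow(species, villages_high, villages_moderate,
                                     area_suitable_km2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"species": r.species, "villages_high": r.villages_high,
             "villages_moderate": r.villages_moderate,
             "area_km2": r.area_suitable_km2} for r in self.rows
        ])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path) -> None:
        self.to_frame().to_json(path, orient="records", indent=2)


def villages_at_risk(villages: VillagePoints, class_map: RiskClassMap
                     ) -> tuple[int, int]:
    """Count villages on high-risk and moderate-risk cells.

    Each village takes the class of its containing cell (half-open cell
    membership: closed left and bottom edges).  Villages outside the extent
    or on nodata cells are dropped with a logged count.
    Returns ``(n_high, n_moderate)``.
    """
    if class_map.grid.size == 0:
        raise ValueError("class map is empty")
    if len(villages) == 0:
        return 0, 0
    cells, inside = points_to_cells(villages.points, class_map.transform,
                                    class_map.grid.shape)
    n_high = n_moderate = 0
    n_dropped = int((~inside).sum())
    for (r, c), ok in zip(cells, inside):
        if not ok:
            continue
        if class_map.nodata_mask[r, c]:
            n_dropped += 1
            continue
        cls = class_map.grid[r, c]
        if cls == 2:
            n_high += 1
        elif cls == 1:
            n_moderate += 1
    if n_dropped:
        logger.info("villages_at_risk: dropped %d of %d villages (outside "
                    "extent or nodata)", n_dropped, len(villages))
    return n_high, n_moderate


def suitable_area(binary_or_class_map, cell_area_km2=1.0,
                  latitudes_deg: np.ndarray | None = None) -> float:
    """Total area of suitable cells.

    Accepts a binary grid (1 = suitable) or a :class:`RiskClassMap`
    (suitable = class >= 1).  ``cell_area_km2`` is either a scalar or a
    per-row vector.  Alternatively pass ``latitudes_deg`` (row-centre
    latitudes of a geographic grid) and a scalar equatorial cell area to
    apply cos(latitude) scaling per row.
    """
    if isinstance(binary_or_class_map, RiskClassMap):
        grid = binary_or_class_map.grid
        suitable = (grid >= 1) & ~binary_or_class_map.nodata_mask
    else:
        grid = np.asarray(binary_or_class_map, dtype=float)
        suitable = grid >= 1
        suitable &= ~np.isnan(grid)
    area = np.asarray(cell_area_km2, dtype=float)
    if np.any(area <= 0):
        raise ValueError("cell_area_km2 must be positive")
    if latitudes_deg is not None:
        lat = np.asarray(latitudes_deg, dtype=float)
        if lat.shape != (suitable.shape[0],):
            raise ValueError("latitudes_deg must have one value per row")
        area = area * np.cos(np.deg2rad(lat))
    if area.ndim == 0:
        return float(suitable.sum() * area)
    if area.shape != (suitable.shape[0],):
        raise ValueError("per-row cell areas must have one value per row")
    return float((suitable.sum(axis=1) * area).sum())
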