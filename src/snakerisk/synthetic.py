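"""Virtual landscapes, virtual species, presence samples and settlements.

Every downstream stage of the risk pipeline is exercised on synthetic data
with known structure: spatially autocorrelated, mutually correlated
environmental layers with low collinearity; species whose true suitability
is a known logistic-linear function of a subset of layers; presence points
drawn proportionally to that true suitability; and uniformly scattered
settlement points.  Because the truth is known, ensemble predictions can be
validated by recovery (rank correlation with true suitability, importance
ranking of the true drivers) rather than against withheld field data.

Spatial autocorrelation is produced by Gaussian smoothing of white noise
(kernel width = the requested autocorrelation length, in cells).
Inter-layer correlation is induced by mixing each layer with a shared
smoothed field: layer_i = sign(r_i)*sqrt(|r_i|) * common + sqrt(1-|r_i|) * own_i,
so two layers with targets r_i and r_j realize correlation
sign(r_i)sign(r_j)*sqrt(|r_i r_j|) — equal to the target when all targets
agree.  This keeps the variance inflation of the stack analytically
controllable.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .raster import EnvStack, GridTransform, default_transform

#: Layer names mirroring a seven-predictor climate/topography/vegetation/
#: anthropogenic stack: temperature seasonality, annual precipitation,
#: precipitation seasonality, precipitation of the driest quarter, vegetation
#: greenness, human footprint, topographic heterogeneity.
DEFAULT_LAYER_NAMES = ["bio4", "bio12", "bio15", "bio17", "NDVI", "HFP", "SD"]

#: Default study conditions for the synthetic landscape: 7 layers, moderate
#: spatial autocorrelation (10-cell kernel) and modest inter-layer
#: correlation (0.3), which keeps all VIFs well under the screening cutoff.
DEFAULT_AUTOCORR_LENGTH = 10.0
DEFAULT_TARGET_CORRELATION = 0.3


def default_layer_specs(names: list[str] | None = None,
                        autocorrelation_length: float = DEFAULT_AUTOCORR_LENGTH,
                        target_correlation: float = DEFAULT_TARGET_CORRELATION,
                        ) -> list[tuple[str, float, float]]:
    names = list(names or DEFAULT_LAYER_NAMES)
    return [(n, autocorrelation_length, target_correlation) for n in names]


@dataclass
class VirtualSpecies:
    """A species with known logistic-linear suitability.

    true_suitability = expit(intercept + sum_k coefficients[k] * layer_k),
    evaluated cellwise; NaN on nodata cells.
    """

    species_id: str
    coefficients: dict[str, float]
    intercept: float
    true_suitability: np.ndarray
    nodata_mask: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


@dataclass
class OccurrenceSet:
    """Presence points for one species, in map coordinates."""

    species_id: str
    points: list[tuple[float, float]]
    source_tag: str = "synthetic"

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 2)


@dataclass
class VillagePoints:
    """Settlement points with unique identifiers."""

    points: list[tuple[float, float]]
    ids: list[str]

    def __post_init__(self) -> None:
        if len(self.points) != len(self.ids):
            raise ValueError("points and ids must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("village ids must be unique")

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 2)


def _smooth_standard_field(rng: np.random.Generator, shape: tuple[int, int],
                           length: float) -> np.ndarray:
    """Gaussian white noise smoothed to the given autocorrelation length and
    standardized to mean 0, sd 1."""
    z = rng.standard_normal(shape)
    if length > 0:
        z = ndimage.gaussian_filter(z, sigma=length, mode="reflect")
    z = (z - z.mean()) / z.std()
    return z


def generate_landscape(n_rows: int, n_cols: int,
                       layer_specs: list[tuple[str, float, float]] | None = None,
                       seed: int = 0,
                       nodata_mask: np.ndarray | None = None,
                       cell_size: float = 1.0) -> EnvStack:
    """Generate a standardized multi-layer environmental landscape.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (>= 8 each).
    layer_specs
        List of (name, autocorrelation_length in cells, target pairwise
        correlation with the other layers, |r| < 0.9).  Defaults to the
        seven-layer stack under the package's default conditions.
    seed
        Seeds the random field generator; identical arguments and seed give
        identical grids.
    nodata_mask
        Optional boolean mask of cells to blank out (NaN).
    cell_size
        Cell edge in map units (km under the synthetic equal-area CRS).

    Each layer is standardized to mean ~0, sd ~1 over non-nodata cells.
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("n_rows and n_cols must be >= 8")
    if layer_specs is None:
        layer_specs = default_layer_specs()
    names = [s[0] for s in layer_specs]
    if len(set(names)) != len(names):
        raise ValueError("layer names must be unique")
    for name, length, r in layer_specs:
        if abs(r) >= 0.9:
            raise ValueError(f"|target correlation| must be < 0.9 (layer {name!r})")
        if length < 0:
            raise ValueError(f"autocorrelation length must be >= 0 (layer {name!r})")

    rng = np.random.default_rng(seed)
    shape = (n_rows, n_cols)
    # one shared field drives the inter-layer correlation; smoothed at the
    # mean requested length of the layers that load on it
    loaded = [length for _, length, r in layer_specs if r != 0]
    common_len = float(np.mean(loaded)) if loaded else 0.0
    common = _smooth_standard_field(rng, shape, common_len)

    if nodata_mask is None:
        nodata_mask = np.zeros(shape, dtype=bool)
    else:
        nodata_mask = np.asarray(nodata_mask, dtype=bool)
        if nodata_mask.shape != shape:
            raise ValueError("nodata_mask shape mismatch")
        if nodata_mask.all():
            raise ValueError("nodata_mask leaves no valid cells")

    grids: dict[str, np.ndarray] = {}
    for name, length, r in layer_specs:
        own = _smooth_standard_field(rng, shape, length)
        g = np.sign(r) * np.sqrt(abs(r)) * common + np.sqrt(1 - abs(r)) * own
        valid = g[~nodata_mask]
        g = (g - valid.mean()) / valid.std()
        g = g.astype(float)
        g[nodata_mask] = np.nan
        grids[name] = g

    transform = GridTransform(0.0, 0.0, cell_size, cell_size)
    return EnvStack(layer_names=names, grids=grids, nodata_mask=nodata_mask,
                    transform=transform, crs_tag="projected-equal-area")


def define_virtual_species(stack: EnvStack, coefficients: dict[str, float],
                           intercept: float, species_id: str) -> VirtualSpecies:
    """Define a species whose suitability is logistic-linear in stack layers."""
    unknown = set(coefficients) - set(stack.layer_names)
    if unknown:
        raise ValueError(f"coefficients reference unknown layers: {sorted(unknown)}")
    eta = np.full(stack.shape, float(intercept))
    for name, beta in coefficients.items():
        eta = eta + beta * stack.grids[name]
    suit = expit(eta)
    suit[stack.nodata_mask] = np.nan
    return VirtualSpecies(species_id=species_id, coefficients=dict(coefficients),
                          intercept=float(intercept), true_suitability=suit,
                          nodata_mask=stack.nodata_mask)


def sample_presences(vs: VirtualSpecies, n: int, seed: int = 0,
                     transform: GridTransform | None = None,
                     dedupe_cells: bool = False) -> OccurrenceSet:
    """Draw presence points with cell probability proportional to suitability.

    Points are placed at cell centres.  With ``dedupe_cells`` the draw is
    without replacement over cells (at most one presence per cell), which
    mimics spatial filtering of opportunistic records; off by default.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if transform is None:
        transform = default_transform()
    suit = np.array(vs.true_suitability, dtype=float)
    if vs.nodata_mask is not None:
        suit[vs.nodata_mask] = 0.0
    suit = np.nan_to_num(suit, nan=0.0)
    total = suit.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    flat_p = (suit / total).ravel()
    rng = np.random.default_rng(seed)
    idx = rng.choice(flat_p.size, size=n, replace=not dedupe_cells, p=flat_p)
    rows, cols = np.unravel_index(idx, suit.shape)
    points = [transform.cell_center(r, c) for r, c in zip(rows, cols)]
    return OccurrenceSet(species_id=vs.species_id, points=points,
                         source_tag="synthetic")


def generate_villages(stack: EnvStack, n: int, seed: int = 0) -> VillagePoints:
    """Scatter n settlement points uniformly over the non-nodata extent.

    Points are uniform within cells (continuous coordinates), so no point
    falls exactly on a cell edge almost surely.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    valid = stack.valid_cells()
    if valid.shape[0] == 0:
        raise ValueError("stack has no valid cells to place villages on")
    rng = np.random.default_rng(seed)
    if n == 0:
        return VillagePoints(points=[], ids=[])
    pick = rng.integers(0, valid.shape[0], size=n)
    offs = rng.random(size=(n, 2))
    t = stack.transform
    points = []
    for (r, c), (u, v) in zip(valid[pick], offs):
        x = t.x_origin + (c + u) * t.cell_size_x
        y = t.y_origin - (r + v) * t.cell_size_y
        points.append((x, y))
    ids = [f"v{i:06d}" for i in range(n)]
    return VillagePoints(points=points, ids=ids)


def occurrences_to_csv(occ: OccurrenceSet, path) -> None:
    import pandas as pd

    arr = occ.as_array()
    pd.DataFrame({"species": occ.species_id, "x": arr[:, 0], "y": arr[:, 1]}
                 ).to_csv(path, index=False)


def villages_to_csv(villages: VillagePoints, path) -> None:
    import pandas as pd

    arr = villages.as_array()
    pd.DataFrame({"id": villages.ids, "x": arr[:, 0], "y": arr[:, 1]}
                 ).to_csv(path, index=False)


def occurrences_from_csv(path, species_id: str | None = None) -> list[OccurrenceSet]:
    """Read `species,x,y` CSV into per-species occurrence sets."""
    import pandas as pd

    df = pd.read_csv(path)
    out = []
    for sp, grp in df.groupby("species", sort=True):
        if species_id is not None and sp != species_id:
            continue
        pts = list(zip(grp["x"].astype(float), grp["y"].astype(float)))
        out.append(OccurrenceSet(species_id=str(sp), points=pts, source_tag=str(path)))
    return out


def villages_from_csv(path) -> VillagePoints:
    import pandas as pd

    df = pd.read_csv(path)
    return VillagePoints(points=list(zip(df["x"].astype(float), df["y"].astype(float))),
                         ids=[str(i) for i in df["id"]])
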