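"""Gridded raster containers and plain-text raster I/O.

The package works on aligned multi-layer environmental grids
(:class:`EnvStack`) and single-layer prediction grids
(:class:`SuitabilitySurface`).  Rasters are read and written as ESRI ASCII
grids (``.asc``), a plain-text format understood by all common GIS software;
a multi-layer stack is a directory of one ``.asc`` per layer plus a small
JSON manifest recording layer order and the CRS tag.

Grid geometry follows the usual raster convention: row 0 is the top of the
map, ``transform.y_origin`` is the *top* edge and ``transform.x_origin`` the
left edge.  Point-in-cell membership is half-open so no point ever belongs
to two cells: a point on a cell's left edge belongs to that cell, a point on
its top edge belongs to the cell above.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

NODATA_VALUE = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Affine placement of a north-up grid in map units.

    ``y_origin`` is the y coordinate of the top edge; ``cell_size_y`` is the
    (positive) cell height going downward.
    """

    x_origin: float
    y_origin: float
    cell_size_x: float
    cell_size_y: float

    def cell_of(self, x: float, y: float, shape: tuple[int, int]) -> tuple[int, int] | None:
        """Return (row, col) containing the point, or None if outside.

        Membership: x in [left, right) of the column, y in (top, bottom] of
        the row — i.e. closed on the left and bottom edges.
        """
        n_rows, n_cols = shape
        col = int(np.floor((x - self.x_origin) / self.cell_size_x))
        # closed-at-bottom: y exactly on a cell's top edge goes to the cell above
        row = int(np.ceil((self.y_origin - y) / self.cell_size_y)) - 1
        if 0 <= row < n_rows and 0 <= col < n_cols:
            return row, col
        return None

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x = self.x_origin + (col + 0.5) * self.cell_size_x
        y = self.y_origin - (row + 0.5) * self.cell_size_y
        return x, y

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_origin, self.y_origin, self.cell_size_x, self.cell_size_y)


DEFAULT_TRANSFORM_CELL_KM = 1.0


def default_transform(cell_size: float = DEFAULT_TRANSFORM_CELL_KM) -> GridTransform:
    return GridTransform(0.0, 0.0, cell_size, cell_size)


@dataclass
class EnvStack:
    """Aligned multi-layer environmental predictor stack.

    All layers share shape, transform, and a single nodata mask.  Values on
    masked cells are NaN; values off the mask are finite.
    """

    layer_names: list[str]
    grids: dict[str, np.ndarray]
    nodata_mask: np.ndarray
    transform: GridTransform = field(default_factory=default_transform)
    crs_tag: str = "projected-equal-area"

    def __post_init__(self) -> None:
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer_names must be unique")
        if set(self.layer_names) != set(self.grids):
            raise ValueError("grids keys must match layer_names")
        shape = self.shape
        if self.nodata_mask.shape != shape:
            raise ValueError("nodata_mask shape mismatch")
        for name in self.layer_names:
            g = self.grids[name]
            if g.shape != shape:
                raise ValueError(f"layer {name!r} shape mismatch")
            vals = g[~self.nodata_mask]
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"layer {name!r} has non-finite values off the nodata mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids[self.layer_names[0]].shape

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    def valid_cells(self) -> np.ndarray:
        """(k, 2) array of (row, col) indices of non-nodata cells."""
        return np.argwhere(~self.nodata_mask)

    def layer(self, name: str) -> np.ndarray:
        return self.grids[name]

    def subset(self, names: Sequence[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.grids]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack(
            layer_names=list(names),
            grids={n: self.grids[n] for n in names},
            nodata_mask=self.nodata_mask,
            transform=self.transform,
            crs_tag=self.crs_tag,
        )

    def cell_values(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """(len(rows), n_layers) matrix of layer values at given cells."""
        return np.column_stack([self.grids[n][rows, cols] for n in self.layer_names])

    def table(self) -> tuple[np.ndarray, np.ndarray]:
        """All non-nodata cells as ((k,2) cell indices, (k, n_layers) values)."""
        cells = self.valid_cells()
        return cells, self.cell_values(cells[:, 0], cells[:, 1])

    # -- persistence ---------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in self.layer_names:
            write_ascii_grid(directory / f"{name}.asc", self.grids[name],
                             self.transform, self.nodata_mask)
        manifest = {"layer_names": self.layer_names, "crs_tag": self.crs_tag}
        (directory / "stack.json").write_text(json.dumps(manifest, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "EnvStack":
        directory = Path(directory)
        manifest = json.loads((directory / "stack.json").read_text())
        grids = {}
        transform = None
        mask = None
        for name in manifest["layer_names"]:
            grid, t, m = read_ascii_grid(directory / f"{name}.asc")
            grids[name] = grid
            transform, mask = t, m
        return cls(layer_names=manifest["layer_names"], grids=grids,
                   nodata_mask=mask, transform=transform,
                   crs_tag=manifest.get("crs_tag", "projected-equal-area"))


@dataclass
class SuitabilitySurface:
    """A [0, 1] prediction grid for one species and one method (or ensemble)."""

    grid: np.ndarray
    nodata_mask: np.ndarray
    species_id: str
    method: str
    transform: GridTransform = field(default_factory=default_transform)

    def __post_init__(self) -> None:
        if self.grid.shape != self.nodata_mask.shape:
            raise ValueError("grid and nodata_mask shape mismatch")
        vals = self.grid[~self.nodata_mask]
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1] off the mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def values(self) -> np.ndarray:
        """Off-mask values, flattened."""
        return self.grid[~self.nodata_mask]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        write_ascii_grid(path, self.grid, self.transform, self.nodata_mask)
        return path


def write_ascii_grid(path: str | Path, grid: np.ndarray, transform: GridTransform,
                     nodata_mask: np.ndarray | None = None) -> Path:
    """Write a 2D grid as an ESRI ASCII raster (square cells only)."""
    path = Path(path)
    if abs(transform.cell_size_x - transform.cell_size_y) > 1e-12:
        raise ValueError("ASCII grid format requires square cells")
    n_rows, n_cols = grid.shape
    out = np.array(grid, dtype=float, copy=True)
    if nodata_mask is not None:
        out[nodata_mask] = NODATA_VALUE
    yll = transform.y_origin - n_rows * transform.cell_size_y
    header = (
        f"ncols {n_cols}\n"
        f"nrows {n_rows}\n"
        f"xllcorner {transform.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {transform.cell_size_x!r}\n"
        f"NODATA_value {NODATA_VALUE!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridTransform, np.ndarray]:
    """Read an ESRI ASCII raster; returns (grid, transform, nodata_mask)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            key = key.lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:  # header shorter than six lines; rewind
                fh.seek(pos)
                break
        fh.seek(pos)
        grid = np.loadtxt(fh).reshape(int(header["nrows"]), int(header["ncols"]))
    cell = header["cellsize"]
    transform = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + int(header["nrows"]) * cell,
        cell_size_x=cell,
        cell_size_y=cell,
    )
    nodata = header.get("nodata_value", NODATA_VALUE)
    mask = grid == nodata
    grid = grid.astype(float)
    grid[mask] = np.nan
    return grid, transform, mask


def points_to_cells(points: Iterable[tuple[float, float]], transform: GridTransform,
                    shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Map points to cell indices.

    Returns (cells, inside): ``cells`` is (n, 2) int with (-1, -1) for points
    outside the extent, ``inside`` a boolean mask of points that landed in a
    cell.
    """
    pts = list(points)
    cells = np.full((len(pts), 2), -1, dtype=int)
    inside = np.zeros(len(pts), dtype=bool)
    for i, (x, y) in enumerate(pts):
        rc = transform.cell_of(x, y, shape)
        if rc is not None:
            cells[i] = rc
            inside[i] = True
    return cells, inside
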