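"""Grid data model and neighborhood/distance primitives.

A :class:`Grid` is a single-band, north-up, square-cell raster with world
coordinates attached to cell centers.  Conventions used throughout the
package:

* arrays are row-major ``(row, col)`` with row 0 at the north edge;
* ``origin_x``/``origin_y`` are the world coordinates of the grid's
  top-left *corner* in meters;
* all distances are meters, all areas km².

Grids are serialized as ESRI ASCII grid (``.asc``) files, a plain-text
interchange format readable by every mainstream GIS.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "Mask",
    "resample",
    "focal_stat",
    "distance_to",
    "buffer_mask",
    "area_km2",
    "read_ascii",
    "write_ascii",
]

Kind = Literal["continuous", "categorical"]


@dataclasses.dataclass
class Grid:
    """Single-band georeferenced raster.

    Parameters
    ----------
    values
        2-D array.  Continuous grids hold floats, categorical grids hold
        integer class codes.
    nodata
        Sentinel value marking cells outside the valid domain.
    origin_x, origin_y
        World coordinates (m) of the top-left corner of cell ``(0, 0)``.
    cell_size
        Square cell edge length in meters; must be positive.
    kind
        ``"continuous"`` or ``"categorical"``.
    """

    values: np.ndarray
    nodata: float = -9999.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 60.0
    kind: Kind = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.kind == "categorical" and not np.issubdtype(
            self.values.dtype, np.integer
        ):
            raise ValueError("categorical grids must hold integer codes")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin_x == other.origin_x
            and self.origin_y == other.origin_y
        )

    def valid(self) -> np.ndarray:
        """Boolean array of cells that are not nodata (and finite)."""
        v = self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            v &= np.isfinite(self.values)
        return v

    # -- coordinate transforms (cell centers) -----------------------------
    def xy_of(self, row, col):
        """World coordinates of cell centers."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def rowcol_of(self, x, y):
        """Cells containing world points (no bounds check)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size)
        return row.astype(int), col.astype(int)

    def contains(self, x, y) -> np.ndarray:
        row, col = self.rowcol_of(x, y)
        return (
            (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        )

    def copy_with(self, values: np.ndarray, kind: Kind | None = None) -> "Grid":
        return Grid(
            values=values,
            nodata=self.nodata,
            origin_x=self.origin_x,
            origin_y=self.origin_y,
            cell_size=self.cell_size,
            kind=kind or self.kind,
        )


class Mask:
    """Boolean membership grid sharing the geometry of a parent :class:`Grid`."""

    def __init__(self, values: np.ndarray, like: Grid):
        values = np.asarray(values, dtype=bool)
        if values.shape != like.shape:
            raise ValueError("mask shape must match parent grid")
        self.values = values
        self.grid = Grid(
            values=values.astype(np.uint8),
            nodata=255,
            origin_x=like.origin_x,
            origin_y=like.origin_y,
            cell_size=like.cell_size,
            kind="categorical",
        )

    @property
    def cell_size(self) -> float:
        return self.grid.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.values & other.values, self.grid)

    def __or__(self, other: "Mask") -> "Mask":
        return Mask(self.values | other.values, self.grid)

    def __invert__(self) -> "Mask":
        return Mask(~self.values, self.grid)

    def difference(self, other: "Mask") -> "Mask":
        return Mask(self.values & ~other.values, self.grid)


# ---------------------------------------------------------------------------
# neighborhood machinery


def disk_offsets(radius_m: float, cell_size: float) -> np.ndarray:
    """(dr, dc) offsets whose cell centers lie within ``radius_m`` (inclusive)."""
    r_cells = int(np.floor(radius_m / cell_size + 1e-9))
    rng = np.arange(-r_cells, r_cells + 1)
    dr, dc = np.meshgrid(rng, rng, indexing="ij")
    d = np.hypot(dr, dc) * cell_size
    keep = d <= radius_m + 1e-9
    return np.column_stack([dr[keep], dc[keep]])


def _disk_footprint(radius_m: float, cell_size: float) -> np.ndarray:
    r_cells = int(np.floor(radius_m / cell_size + 1e-9))
    rng = np.arange(-r_cells, r_cells + 1)
    dr, dc = np.meshgrid(rng, rng, indexing="ij")
    return (np.hypot(dr, dc) * cell_size) <= radius_m + 1e-9


def focal_stat(grid: Grid, radius: float, stat: str = "mean") -> Grid:
    """Circular focal statistic.

    Membership uses the cell-center rule (center within ``radius`` of the
    focal center, inclusive).  Nodata cells are excluded; neighborhoods
    shrink at grid edges.  A neighborhood with no valid cell yields nodata.
    """
    if radius < grid.cell_size:
        raise ValueError(
            f"radius {radius} m is smaller than the cell size {grid.cell_size} m"
        )
    if stat != "mean":
        raise ValueError(f"unsupported stat: {stat!r}")
    fp = _disk_footprint(radius, grid.cell_size)
    valid = grid.valid()
    vals = np.where(valid, grid.values.astype(float), 0.0)
    ssum = ndimage.correlate(vals, fp.astype(float), mode="constant", cval=0.0)
    cnt = ndimage.correlate(
        valid.astype(float), fp.astype(float), mode="constant", cval=0.0
    )
    out = np.full(grid.shape, grid.nodata, dtype=float)
    ok = cnt > 0.5
    out[ok] = ssum[ok] / cnt[ok]
    return grid.copy_with(out, kind="continuous")


def resample(grid: Grid, target_cell: float) -> Grid:
    """Resample to a new square cell size covering the same extent.

    Continuous grids are bilinearly interpolated between cell centers;
    categorical grids use nearest-neighbor (class codes cannot be averaged).
    Nodata cells poison any bilinear interpolation they participate in.
    """
    if target_cell <= 0:
        raise ValueError("target_cell must be positive")
    height = grid.nrows * grid.cell_size
    width = grid.ncols * grid.cell_size
    nrows = max(1, int(round(height / target_cell)))
    ncols = max(1, int(round(width / target_cell)))
    # target cell centers in source fractional-index space
    rows = (np.arange(nrows) + 0.5) * target_cell / grid.cell_size - 0.5
    cols = (np.arange(ncols) + 0.5) * target_cell / grid.cell_size - 0.5
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    if grid.kind == "categorical":
        ri = np.clip(np.rint(rr), 0, grid.nrows - 1).astype(int)
        ci = np.clip(np.rint(cc), 0, grid.ncols - 1).astype(int)
        out = grid.values[ri, ci]
    else:
        vals = grid.values.astype(float)
        bad = ~grid.valid()
        work = np.where(bad, np.nan, vals)
        out = ndimage.map_coordinates(
            work, [rr, cc], order=1, mode="nearest", cval=np.nan
        )
        out = np.where(np.isfinite(out), out, grid.nodata)
    return Grid(
        values=out,
        nodata=grid.nodata,
        origin_x=grid.origin_x,
        origin_y=grid.origin_y,
        cell_size=target_cell,
        kind=grid.kind,
    )


def distance_to(mask: Mask) -> Grid:
    """Euclidean distance (m) from each cell center to the nearest member cell."""
    if mask.count() == 0:
        raise ValueError("distance_to requires a non-empty mask")
    d = ndimage.distance_transform_edt(~mask.values) * mask.cell_size
    return mask.grid.copy_with(d.astype(float), kind="continuous")


def buffer_mask(mask: Mask, radius: float) -> Mask:
    """Union of the mask with every cell whose center lies within ``radius``."""
    if radius < 0:
        raise ValueError("radius must be non-negative")
    if radius == 0 or mask.count() == 0:
        return Mask(mask.values.copy(), mask.grid)
    d = ndimage.distance_transform_edt(~mask.values) * mask.cell_size
    return Mask(d <= radius + 1e-9, mask.grid)


def area_km2(mask: Mask) -> float:
    """Member-cell count × cell area, in km²."""
    return mask.count() * mask.cell_size**2 / 1e6


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def write_ascii(grid: Grid, path: str | Path) -> None:
    path = Path(path)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin_x}\n"
        f"yllcorner {grid.origin_y - grid.nrows * grid.cell_size}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    fmt = "%d" if grid.kind == "categorical" else "%.8g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt=fmt)
    meta = {"kind": grid.kind}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_ascii(path: str | Path, kind: Kind | None = None) -> Grid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if kind is None:
        side = Path(str(path) + ".json")
        kind = (
            json.loads(side.read_text()).get("kind", "continuous")
            if side.exists()
            else "continuous"
        )
    if kind == "categorical":
        values = values.astype(np.int64)
    return Grid(
        values=values,
        nodata=header.get("nodata_value", -9999.0),
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + header["nrows"] * header["cellsize"],
        cell_size=header["cellsize"],
        kind=kind,
    )
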