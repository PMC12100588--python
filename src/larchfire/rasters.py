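"""Single-band raster grids with plain-text (ESRI ASCII grid) I/O.

Grids are north-up with square pixels; values are float arrays with NaN as
the in-memory missing marker. The on-disk format is the ESRI ASCII grid
(.asc) with an optional .prj sidecar carrying the CRS tag. Reprojection and
rotated affine transforms are out of scope by design.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

log = logging.getLogger(__name__)


class RasterFormatError(ValueError):
    """Unsupported raster geometry or malformed file."""


class AlignmentError(ValueError):
    """Raster grids do not share one 30 m grid."""


@dataclass
class RasterGrid:
    """values[row, col] with row 0 at the northern edge."""

    values: np.ndarray  # 2-D float array, NaN = nodata
    x_origin: float  # west edge (left of column 0)
    y_origin: float  # north edge (top of row 0)
    pixel_size: float
    crs: str | None = None
    band: str = ""
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RasterFormatError("raster values must be a 2-D array")
        if self.pixel_size <= 0:
            raise RasterFormatError("pixel size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def x_edges(self) -> np.ndarray:
        return self.x_origin + self.pixel_size * np.arange(self.shape[1] + 1)

    def y_edges(self) -> np.ndarray:
        """Northern-most edge first, decreasing southwards."""
        return self.y_origin - self.pixel_size * np.arange(self.shape[0] + 1)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.x_origin + self.pixel_size * (np.arange(self.shape[1]) + 0.5)
        ys = self.y_origin - self.pixel_size * (np.arange(self.shape[0]) + 0.5)
        return xs, ys

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and abs(self.x_origin - other.x_origin) < 1e-6
            and abs(self.y_origin - other.y_origin) < 1e-6
            and abs(self.pixel_size - other.pixel_size) < 1e-9
        )


def write_raster(grid: RasterGrid, path: str | Path) -> None:
    path = Path(path)
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    nrows, ncols = grid.shape
    yll = grid.y_origin - nrows * grid.pixel_size
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.pixel_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")
    if grid.crs:
        path.with_suffix(".prj").write_text(grid.crs + "\n")


def read_raster(path: str | Path, band: str = "") -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.atleast_2d(values).reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    prj = path.with_suffix(".prj")
    crs = prj.read_text().strip() if prj.exists() else None
    if crs is None:
        warnings.warn(f"raster {path.name} carries no CRS tag", stacklevel=2)
    return RasterGrid(
        values=values,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * header["cellsize"],
        pixel_size=header["cellsize"],
        crs=crs,
        band=band or path.stem,
        nodata=nodata,
    )


def reproject(*args, **kwargs):
    """Geodetic reprojection is a declared non-goal."""
    raise NotImplementedError(
        "reprojection is not supported; supply rasters already on a common projected grid"
    )


def regrid_bilinear(grid: RasterGrid, pixel_size: float) -> RasterGrid:
    """Bilinear resampling onto a coarser/finer grid with the same extent.

    Preserves a constant field exactly; NaNs propagate to any target cell
    whose four surrounding source centers include one.
    """
    nrows, ncols = grid.shape
    width = ncols * grid.pixel_size
    height = nrows * grid.pixel_size
    out_cols = max(int(round(width / pixel_size)), 1)
    out_rows = max(int(round(height / pixel_size)), 1)
    xs = grid.x_origin + pixel_size * (np.arange(out_cols) + 0.5)
    ys = grid.y_origin - pixel_size * (np.arange(out_rows) + 0.5)
    # fractional source indices of target centers
    fx = (xs - grid.x_origin) / grid.pixel_size - 0.5
    fy = (grid.y_origin - ys) / grid.pixel_size - 0.5
    fx = np.clip(fx, 0, ncols - 1)
    fy = np.clip(fy, 0, nrows - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, ncols - 1)
    y0 = np.clip(np.floor(fy).astype(int), 0, nrows - 1)
    x1 = np.minimum(x0 + 1, ncols - 1)
    y1 = np.minimum(y0 + 1, nrows - 1)
    wx = fx - x0
    wy = fy - y0
    V = grid.values
    out = (
        V[np.ix_(y0, x0)] * np.outer(1 - wy, 1 - wx)
        + V[np.ix_(y0, x1)] * np.outer(1 - wy, wx)
        + V[np.ix_(y1, x0)] * np.outer(wy, 1 - wx)
        + V[np.ix_(y1, x1)] * np.outer(wy, wx)
    )
    return RasterGrid(out, grid.x_origin, grid.y_origin, pixel_size, grid.crs, grid.band, grid.nodata)
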