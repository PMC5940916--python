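"""Raster grid data model, Esri ASCII I/O, resampling, terrain derivatives
and the Euclidean distance transform.

Coordinates are planar metres with no CRS.  The grid origin is the outer
corner of the upper-left cell; the row index increases southward (raster
convention), so the centre of cell (row, col) is at

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

Grain size is simply ``cell_size``; the study manipulates it over
50 m, 300 m and 1 km.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """One raster layer: a rectangular cell array plus geometry metadata.

    Parameters
    ----------
    values : 2-D ndarray
        Cell values, row 0 at the top (north).
    origin : (float, float)
        Planar (x, y) of the outer corner of the upper-left cell.
    cell_size : float
        Square cell edge length in metres; must be positive.
    nodata : float
        Sentinel marking missing cells.
    kind : {"continuous", "categorical"}
        Categorical grids hold integer class codes (or nodata) and are
        resampled with nearest-neighbour; continuous grids bilinearly.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 50.0
    nodata: float = DEFAULT_NODATA
    kind: str = CONTINUOUS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("grid values must be a 2-D array with >= 1 row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.kind == CATEGORICAL:
            v = self.values[self.mask()]
            if v.size and not np.allclose(v, np.round(v)):
                raise ValueError("categorical grid contains non-integer codes")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def mask(self) -> np.ndarray:
        """Boolean array of valid (finite, non-nodata) cells."""
        return np.isfinite(self.values) & (self.values != self.nodata)

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid boundary."""
        x0, y0 = self.origin
        return (x0, x0 + self.n_cols * self.cell_size,
                y0 - self.n_rows * self.cell_size, y0)

    def cell_center(self, rows, cols) -> tuple[np.ndarray, np.ndarray]:
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        x0, y0 = self.origin
        return (x0 + (cols + 0.5) * self.cell_size,
                y0 - (rows + 0.5) * self.cell_size)

    def world_to_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (may fall outside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - y) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.world_to_index(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def value_at(self, x, y) -> np.ndarray:
        """Cell value at each point; nodata for points off the grid."""
        row, col = self.world_to_index(x, y)
        inside = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out = np.full(row.shape, self.nodata, dtype=float)
        out[inside] = self.values[row[inside], col[inside]]
        return out

    def same_geometry(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (self.shape == other.shape
                and abs(self.cell_size - other.cell_size) <= tol
                and abs(self.origin[0] - other.origin[0]) <= tol
                and abs(self.origin[1] - other.origin[1]) <= tol)

    def copy_with(self, **kwargs) -> "Grid":
        if "values" in kwargs:
            kwargs["values"] = np.array(kwargs["values"], dtype=float)
        else:
            kwargs["values"] = self.values.copy()
        return replace(self, **kwargs)


# -- Esri ASCII grid I/O ----------------------------------------------------

def write_ascii(grid: Grid, path) -> None:
    """Write an Esri ASCII grid (.asc).  Round-trips bit-faithfully."""
    x0, y0 = grid.origin
    yll = y0 - grid.n_rows * grid.cell_size
    fmt = "%d" if grid.kind == CATEGORICAL else "%.17g"
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {x0:.17g}\n")
        fh.write(f"yllcorner {yll:.17g}\n")
        fh.write(f"cellsize {grid.cell_size:.17g}\n")
        fh.write(f"NODATA_value {grid.nodata:.17g}\n")
        vals = grid.values
        if grid.kind == CATEGORICAL:
            # nodata may be non-integer; emit it literally
            for r in range(grid.n_rows):
                row = vals[r]
                fh.write(" ".join(
                    f"{grid.nodata:.17g}" if (not np.isfinite(v) or v == grid.nodata)
                    else f"{int(round(v))}"
                    for v in row))
                fh.write("\n")
        else:
            np.savetxt(fh, vals, fmt=fmt)


def read_ascii(path, kind: str = CONTINUOUS) -> Grid:
    """Read an Esri ASCII grid written with :func:`write_ascii`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                    "ncols", "nrows", "xllcorner", "yllcorner",
                    "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
            if key not in header:
                raise ValueError(f"Esri ASCII header missing {key!r} in {path}")
        values = np.loadtxt(fh, dtype=float, ndmin=2)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"grid body {values.shape} does not match header "
                         f"({n_rows}, {n_cols}) in {path}")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    return Grid(values, origin=origin, cell_size=cell, nodata=nodata, kind=kind)


# -- resampling -------------------------------------------------------------

def _nearest_index(frac: np.ndarray, n: int) -> np.ndarray:
    # tie at exactly .5 between two centres resolves to the smaller index
    idx = np.ceil(frac - 0.5).astype(int)
    return np.clip(idx, 0, n - 1)


def resample(grid: Grid, target_cell_size: float) -> Grid:
    """Resample to a new grain, evaluating at target cell centres.

    Categorical grids use nearest-neighbour (ties resolve to the smallest
    row, then smallest column index); continuous grids use bilinear
    interpolation over the four surrounding source cell centres.  Nodata
    propagates from any source cell that carries positive interpolation
    weight.  The output covers the same extent truncated to whole target
    cells anchored at the origin.
    """
    if not target_cell_size > 0:
        raise ValueError("target_cell_size must be > 0")
    s, t = grid.cell_size, float(target_cell_size)
    n_rows = int(grid.n_rows * s // t)
    n_cols = int(grid.n_cols * s // t)
    if n_rows < 1 or n_cols < 1:
        raise ValueError(
            f"target cell size {t} m collapses the {grid.n_rows}x{grid.n_cols} "
            f"grid at {s} m to zero cells")

    # fractional source-centre coordinates of each target cell centre
    fr = ((np.arange(n_rows) + 0.5) * t) / s - 0.5
    fc = ((np.arange(n_cols) + 0.5) * t) / s - 0.5

    if grid.kind == CATEGORICAL:
        ri = _nearest_index(fr, grid.n_rows)
        ci = _nearest_index(fc, grid.n_cols)
        out = grid.values[np.ix_(ri, ci)]
    else:
        out = _bilinear(grid, fr, fc)
    return Grid(out, origin=grid.origin, cell_size=t,
                nodata=grid.nodata, kind=grid.kind)


def _bilinear(grid: Grid, fr: np.ndarray, fc: np.ndarray) -> np.ndarray:
    nr, nc = grid.shape
    fr = np.clip(fr, 0.0, nr - 1.0)
    fc = np.clip(fc, 0.0, nc - 1.0)
    r0 = np.clip(np.floor(fr).astype(int), 0, max(nr - 2, 0))
    c0 = np.clip(np.floor(fc).astype(int), 0, max(nc - 2, 0))
    wr = (fr - r0)[:, None]
    wc = (fc - c0)[None, :]
    r1 = np.minimum(r0 + 1, nr - 1)
    c1 = np.minimum(c0 + 1, nc - 1)

    v = grid.values
    q00 = v[np.ix_(r0, c0)]
    q01 = v[np.ix_(r0, c1)]
    q10 = v[np.ix_(r1, c0)]
    q11 = v[np.ix_(r1, c1)]
    w00 = (1 - wr) * (1 - wc)
    w01 = (1 - wr) * wc
    w10 = wr * (1 - wc)
    w11 = wr * wc
    out = q00 * w00 + q01 * w01 + q10 * w10 + q11 * w11

    bad = np.zeros(out.shape, dtype=bool)
    for q, w in ((q00, w00), (q01, w01), (q10, w10), (q11, w11)):
        invalid = ~np.isfinite(q) | (q == grid.nodata)
        bad |= invalid & (w > 0)
    out[bad] = grid.nodata
    return out


# -- terrain derivatives ----------------------------------------------------

def slope_aspect(dem: Grid) -> tuple[Grid, Grid]:
    """Slope and aspect from a DEM via Horn's 3x3 finite differences.

    Slope is in degrees from horizontal.  Aspect is in degrees clockwise
    from grid north, pointing downslope; flat cells get nodata aspect.
    Border cells use edge replication.  Requires a continuous DEM of at
    least 3x3 cells.
    """
    if dem.kind != CONTINUOUS:
        raise ValueError("slope_aspect requires a continuous DEM")
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("DEM must be at least 3x3 for slope/aspect")
    valid = dem.mask()
    z = np.where(valid, dem.values, np.nan)
    zp = np.pad(z, 1, mode="edge")

    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]

    cs = dem.cell_size
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)   # east
    dz_dy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)   # north

    grad = np.hypot(dz_dx, dz_dy)
    slope = np.degrees(np.arctan(grad))

    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy)) % 360.0
    flat = grad == 0

    nod = dem.nodata
    slope_vals = np.where(np.isfinite(slope), slope, nod)
    aspect_vals = np.where(np.isfinite(aspect) & ~flat, aspect, nod)
    slope_vals = np.where(valid, slope_vals, nod)
    aspect_vals = np.where(valid, aspect_vals, nod)

    geo = dict(origin=dem.origin, cell_size=dem.cell_size, nodata=nod, kind=CONTINUOUS)
    return Grid(slope_vals, **geo), Grid(aspect_vals, **geo)


# -- distance transform -----------------------------------------------------

def distance_to_channels(mask: Grid) -> Grid:
    """Exact Euclidean distance (metres) from each cell centre to the
    nearest channel-cell centre.  ``mask`` is categorical with codes
    {0, 1}; at least one channel (1) cell is required.
    """
    if mask.kind != CATEGORICAL:
        raise ValueError("channel mask must be categorical")
    vals = mask.values
    codes = np.unique(vals[mask.mask()])
    if not np.all(np.isin(codes, (0.0, 1.0))):
        raise ValueError("channel mask codes must be {0, 1}")
    channel = vals == 1
    if not channel.any():
        raise ValueError("channel mask contains no channel (code 1) cell")
    dist = ndimage.distance_transform_edt(~channel, sampling=mask.cell_size)
    return Grid(dist, origin=mask.origin, cell_size=mask.cell_size,
                nodata=mask.nodata, kind=CONTINUOUS)
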