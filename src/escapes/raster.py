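"""Minimal planar raster container with ESRI ASCII grid text I/O.

Coordinates are planar meters. A :class:`Raster` stores a ``(ny, nx)`` array
with row 0 at the *bottom* (y increasing with row index), a lower-left corner
origin, and a square cell size. Cells are half-open intervals
``[x0 + ix*cs, x0 + (ix+1)*cs) x [y0 + iy*cs, y0 + (iy+1)*cs)`` so a point on
a shared boundary belongs to exactly one cell.

Categorical habitat grids use integer codes (:data:`OTHER`, :data:`WATER`,
:data:`MARSH`) with ``-1`` as nodata; continuous grids use float arrays with
NaN as nodata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# habitat class codes
OTHER = 0
WATER = 1
MARSH = 2
HABITAT_CODES = (OTHER, WATER, MARSH)
HABITAT_NODATA = -1

__all__ = [
    "Raster",
    "OTHER",
    "WATER",
    "MARSH",
    "HABITAT_CODES",
    "HABITAT_NODATA",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class Raster:
    """A single-band planar raster.

    Parameters
    ----------
    values : ndarray of shape (ny, nx)
        Cell values, row 0 at the bottom (smallest y).
    cell_size : float
        Cell edge length in meters (> 0).
    origin : tuple of float
        ``(x0, y0)`` of the lower-left corner of cell ``(0, 0)``.
    """

    values: np.ndarray
    cell_size: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.cell_size, y0 + ny * self.cell_size)

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Return ``(iy, ix)`` of the cell containing (x, y), or None outside.

        Half-open convention: the lower/left edges belong to a cell, the
        upper/right edges to its neighbour.
        """
        x0, y0 = self.origin
        ix = int(np.floor((x - x0) / self.cell_size))
        iy = int(np.floor((y - y0) / self.cell_size))
        ny, nx = self.values.shape
        if 0 <= ix < nx and 0 <= iy < ny:
            return iy, ix
        return None

    def cell_indices(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized :meth:`cell_of`: returns (iy, ix, inside_mask)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        ix = np.floor((x - x0) / self.cell_size).astype(int)
        iy = np.floor((y - y0) / self.cell_size).astype(int)
        ny, nx = self.values.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        return iy, ix, inside

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of x and y cell-center coordinates."""
        ny, nx = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(nx) + 0.5) * self.cell_size
        ys = y0 + (np.arange(ny) + 0.5) * self.cell_size
        return xs, ys

    def copy_with(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values))


def write_ascii_grid(raster: Raster, path, nodata: float = -9999) -> None:
    """Write an ESRI ASCII grid (.asc); NaN/HABITAT_NODATA become ``nodata``."""
    vals = np.asarray(raster.values, dtype=float).copy()
    if np.issubdtype(raster.values.dtype, np.integer):
        vals[raster.values == HABITAT_NODATA] = nodata
        fmt = "%d"
    else:
        vals[~np.isfinite(vals)] = nodata
        fmt = "%.10g"
    ny, nx = vals.shape
    header = (
        f"ncols {nx}\nnrows {ny}\n"
        f"xllcorner {raster.origin[0]:.10g}\nyllcorner {raster.origin[1]:.10g}\n"
        f"cellsize {raster.cell_size:.10g}\nNODATA_value {nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ASCII grids are written top row first
        np.savetxt(fh, vals[::-1], fmt=fmt)


def read_ascii_grid(path, categorical: bool = False) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)[::-1]
    nodata = header.get("nodata_value", -9999)
    if categorical:
        vals = body.astype(int)
        vals[body == nodata] = HABITAT_NODATA
    else:
        vals = body.astype(float)
        vals[body == nodata] = np.nan
    return Raster(
        values=vals,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
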