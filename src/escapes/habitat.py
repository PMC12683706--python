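"""Resource-producing habitat layers.

Three basal resources are mapped to habitat layers: marsh grass to the marsh
cover class, benthic microalgae to the marsh-water edge, and phytoplankton to
water cover weighted by relative chlorophyll-a. Layer construction follows the
E-scape recipe: edge is the linear marsh-water boundary length times a fixed
width (default 10 m) expressed as an area, and chlorophyll is normalized by
its maximum over the analysis window so the phytoplankton layer is a relative
weight in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import HABITAT_CODES, HABITAT_NODATA, MARSH, OTHER, WATER, Raster

__all__ = [
    "HabitatFractions",
    "aggregate_cover",
    "edge_area",
    "relative_chl",
    "habitat_fractions",
    "disk_offsets",
]


class MappingError(ValueError):
    """A raw cover class has no marsh/water/other assignment."""


class GeometryError(ValueError):
    """Rasters are misaligned or a point falls outside valid geometry."""


class EmptyBufferError(ValueError):
    """A sampling buffer contains no valid habitat cells."""


@dataclass(frozen=True)
class HabitatFractions:
    """Areal fractions of the three resource-producing layers in a region.

    ``f_marsh`` and ``f_phyto`` are fractions of the valid buffer area;
    ``f_edge`` is derived edge area over buffer area and may exceed what a
    partition would allow (edge is a linear feature expressed as area).
    """

    f_marsh: float
    f_edge: float
    f_phyto: float
    area: float  # valid buffer area, m^2

    def as_array(self) -> np.ndarray:
        """Order matches the source simplex (phytoplankton, benthic, marsh)."""
        return np.array([self.f_phyto, self.f_edge, self.f_marsh])


def aggregate_cover(raw: Raster, mapping: dict[int, int]) -> Raster:
    """Collapse a many-class cover raster to {marsh, water, other}.

    Parameters
    ----------
    raw : Raster
        Integer-coded cover classes; ``HABITAT_NODATA`` passes through.
    mapping : dict
        raw class code -> one of MARSH, WATER, OTHER. Every code present in
        the raster must be mapped.
    """
    vals = np.asarray(raw.values)
    present = set(np.unique(vals).tolist()) - {HABITAT_NODATA}
    unmapped = sorted(present - set(mapping))
    if unmapped:
        raise MappingError(f"unmapped cover classes: {unmapped}")
    bad_targets = {v for v in mapping.values() if v not in HABITAT_CODES}
    if bad_targets:
        raise MappingError(f"mapping targets outside habitat codes: {sorted(bad_targets)}")
    out = np.full(vals.shape, HABITAT_NODATA, dtype=np.int64)
    for code, target in mapping.items():
        out[vals == code] = target
    out[vals == HABITAT_NODATA] = HABITAT_NODATA
    return raw.copy_with(out)


def edge_area(hab: Raster, width: float = 10.0, side: str = "water") -> Raster:
    """Marsh-water edge expressed as area (m^2) accumulated per cell.

    Each 4-neighbour marsh-water adjacency contributes one boundary segment of
    length ``cell_size``; the segment's area is ``cell_size * width``. The
    area is credited to the cell on ``side`` ("water", the default, matching
    where benthic algae production is sampled, or "marsh"). Total edge area is
    identical for either side.
    """
    if side not in ("water", "marsh"):
        raise ValueError("side must be 'water' or 'marsh'")
    vals = hab.values
    marsh = vals == MARSH
    water = vals == WATER
    counts = np.zeros(vals.shape, dtype=np.int64)
    receiver, other_cls = (water, marsh) if side == "water" else (marsh, water)
    # count, for each receiver cell, 4-neighbours of the opposite class
    for shift, axis in ((1, 0), (-1, 0), (1, 1), (-1, 1)):
        neighb = np.roll(other_cls, shift, axis=axis)
        # roll wraps around; zero out the wrapped slab
        if axis == 0:
            if shift == 1:
                neighb[0, :] = False
            else:
                neighb[-1, :] = False
        else:
            if shift == 1:
                neighb[:, 0] = False
            else:
                neighb[:, -1] = False
        counts += receiver & neighb
    area = counts * hab.cell_size * width
    return hab.copy_with(area.astype(float))


def relative_chl(stack: list[Raster] | Raster) -> Raster:
    """Cellwise mean of a window of chlorophyll rasters, scaled by its max.

    The output is in [0, 1] over valid cells with the maximum exactly 1 (the
    chlorophyll layer is a relative weight, not a concentration).
    """
    if isinstance(stack, Raster):
        stack = [stack]
    if not stack:
        raise ValueError("need at least one chlorophyll raster")
    ref = stack[0]
    for r in stack[1:]:
        if not r.aligned_with(ref):
            raise GeometryError("chlorophyll rasters are not aligned")
    cube = np.stack([np.asarray(r.values, dtype=float) for r in stack])
    finite = np.isfinite(cube)
    counts = finite.sum(axis=0)
    sums = np.where(finite, cube, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if not np.any(np.isfinite(mean)):
        raise ValueError("no valid chlorophyll cells in window")
    peak = np.nanmax(mean)
    if peak <= 0:
        raise ValueError("maximum chlorophyll must be positive")
    return ref.copy_with(mean / peak)


def disk_offsets(radius: float, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Row/col offsets of cells whose centers lie within ``radius`` of a
    reference cell center (the center-in-circle buffer rule)."""
    r_cells = int(np.floor(radius / cell_size))
    dy, dx = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    keep = (dx * cell_size) ** 2 + (dy * cell_size) ** 2 <= radius**2
    return dy[keep].ravel(), dx[keep].ravel()


def _buffer_cells(hab: Raster, center: tuple[float, float], radius: float):
    """(iy, ix) arrays of in-grid cells in the circular buffer around center."""
    cell = hab.cell_of(*center)
    if cell is None:
        raise GeometryError(f"buffer center {center} outside raster extent")
    iy0, ix0 = cell
    dy, dx = disk_offsets(radius, hab.cell_size)
    iy = iy0 + dy
    ix = ix0 + dx
    ny, nx = hab.shape
    keep = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
    return iy[keep], ix[keep]


def habitat_fractions(
    hab: Raster,
    chl: Raster,
    edge: Raster,
    center: tuple[float, float],
    radius: float = 500.0,
    rule: str = "center",
) -> HabitatFractions:
    """Fractions of the three resource layers in a circular buffer.

    ``rule="center"`` (default) includes cells whose centers fall inside the
    circle; ``rule="exact"`` weights cells by the exact cell-circle
    intersection area (shapely).
    """
    if not (chl.aligned_with(hab) and edge.aligned_with(hab)):
        raise GeometryError("habitat, chlorophyll and edge rasters must be aligned")
    if rule == "center":
        iy, ix = _buffer_cells(hab, center, radius)
        weights = np.ones(iy.size)
    elif rule == "exact":
        iy, ix, weights = _exact_buffer_weights(hab, center, radius)
    else:
        raise ValueError("rule must be 'center' or 'exact'")

    codes = hab.values[iy, ix]
    valid = codes != HABITAT_NODATA
    if not np.any(valid) or weights[valid].sum() == 0:
        raise EmptyBufferError(f"buffer at {center} contains no valid habitat cells")
    w = weights[valid]
    codes = codes[valid]
    cell_area = hab.cell_size**2
    area = w.sum() * cell_area

    marsh_area = w[codes == MARSH].sum() * cell_area
    water_sel = codes == WATER
    chl_vals = np.asarray(chl.values, dtype=float)[iy, ix][valid][water_sel]
    chl_vals = np.nan_to_num(chl_vals, nan=0.0)
    phyto_area = float(np.sum(w[water_sel] * chl_vals)) * cell_area
    edge_a = float(np.sum(w * np.asarray(edge.values, dtype=float)[iy, ix][valid]))

    return HabitatFractions(
        f_marsh=marsh_area / area,
        f_edge=edge_a / area,
        f_phyto=phyto_area / area,
        area=area,
    )


def _exact_buffer_weights(hab: Raster, center: tuple[float, float], radius: float):
    """Cell weights from exact cell-circle intersection areas (0..1)."""
    from shapely.geometry import Point, box

    circle = Point(*center).buffer(radius, quad_segs=64)
    # candidate cells: centers within radius + one cell diagonal
    pad = radius + hab.cell_size * 1.5
    cell = hab.cell_of(
        min(max(center[0], hab.extent[0]), np.nextafter(hab.extent[2], -np.inf)),
        min(max(center[1], hab.extent[1]), np.nextafter(hab.extent[3], -np.inf)),
    )
    if cell is None:  # pragma: no cover - guarded by caller geometry
        raise GeometryError(f"buffer center {center} outside raster extent")
    iy0, ix0 = cell
    r_cells = int(np.ceil(pad / hab.cell_size))
    ny, nx = hab.shape
    x0, y0 = hab.origin
    cs = hab.cell_size
    iys, ixs, ws = [], [], []
    for iy in range(max(0, iy0 - r_cells), min(ny, iy0 + r_cells + 1)):
        for ix in range(max(0, ix0 - r_cells), min(nx, ix0 + r_cells + 1)):
            cell_geom = box(x0 + ix * cs, y0 + iy * cs, x0 + (ix + 1) * cs, y0 + (iy + 1) * cs)
            frac = cell_geom.intersection(circle).area / (cs * cs)
            if frac > 0:
                iys.append(iy)
                ixs.append(ix)
                ws.append(frac)
    return np.array(iys, dtype=int), np.array(ixs, dtype=int), np.array(ws)
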