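"""E-scape construction: IEI calibration and HRI mapping.

The index of energetic importance (IEI) of basal source *i* is the ratio of
the source's dietary contribution fraction (from the isotope mixing model) to
the areal fraction of its producing habitat in a circular buffer:

    IEI_i = fsource_i / fhabitat_i

evaluated at random calibration points; values > 1 mean the consumer uses a
resource disproportionately to its availability. The habitat resource index
(HRI) of a landscape foraging unit *x* recombines the median IEIs with the
unit's own habitat fractions:

    HRI_x = sum_i median(IEI_i) * fhabitat_{i,x}

so HRI = 1 is the landscape-average level of resource production and the
E-scape is the HRI map on a coarse (default 1 km) grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .habitat import (
    EmptyBufferError,
    GeometryError,
    disk_offsets,
    edge_area,
    habitat_fractions,
)
from .raster import HABITAT_NODATA, MARSH, WATER, Raster

logger = logging.getLogger(__name__)

SOURCES = ("phytoplankton", "benthic", "marsh")

__all__ = ["SOURCES", "IEITable", "EScape", "EScapeBuilder", "compute_iei", "compute_hri", "sample_hri"]


@dataclass
class IEITable:
    """Per-point IEI values and their per-source summary.

    Attributes
    ----------
    points : DataFrame
        Columns x, y, source, fhabitat, iei — one row per retained
        point-source pair (points whose buffer lacks the habitat are dropped
        for that source).
    summary : DataFrame
        Columns source, median, q25, q75, n_points.
    dropped : dict
        Per source, number of calibration points without the habitat.
    year : str or None
    """

    points: pd.DataFrame
    summary: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)
    year: str | None = None

    def medians(self) -> np.ndarray:
        """Median IEI per source in :data:`SOURCES` order."""
        med = self.summary.set_index("source")["median"]
        return np.array([med.get(s, np.nan) for s in SOURCES])


@dataclass
class EScape:
    """HRI values on the landscape-foraging-unit grid plus provenance."""

    hri: Raster
    iei: IEITable
    year: str | None = None

    def log_hri(self) -> Raster:
        """log(HRI) with non-positive or nodata cells as NaN (never -inf)."""
        vals = np.asarray(self.hri.values, dtype=float)
        out = np.full(vals.shape, np.nan)
        ok = np.isfinite(vals) & (vals > 0)
        out[ok] = np.log(vals[ok])
        return self.hri.copy_with(out)


def _fractions_stack(hab: Raster, chl: Raster, edge: Raster) -> np.ndarray:
    """Per-cell layer weights stacked (phyto, edge-as-fraction-of-cell, marsh)."""
    vals = hab.values
    chlv = np.nan_to_num(np.asarray(chl.values, dtype=float), nan=0.0)
    cell_area = hab.cell_size**2
    phyto = np.where(vals == WATER, chlv, 0.0)
    edge_frac = np.asarray(edge.values, dtype=float) / cell_area
    marsh = (vals == MARSH).astype(float)
    return np.stack([phyto, edge_frac, marsh])


def compute_iei(
    hab: Raster,
    chl: Raster,
    edge: Raster,
    fsource,
    n_points: int = 1000,
    radius: float = 500.0,
    region_mask: np.ndarray | None = None,
    seed: int | None = None,
    year: str | None = None,
) -> IEITable:
    """Calibrate IEI from random buffer samples.

    Parameters
    ----------
    fsource : array-like of 3
        Median dietary contribution of (phytoplankton, benthic algae, marsh
        grass); must lie on the simplex.
    region_mask : bool array, optional
        Restricts candidate calibration cells; defaults to all valid habitat
        cells.
    """
    fsource = np.asarray(fsource, dtype=float)
    if fsource.shape != (3,) or np.any(fsource < 0) or abs(fsource.sum() - 1) > 1e-6:
        raise ValueError("fsource must be a 3-vector on the simplex")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (chl.aligned_with(hab) and edge.aligned_with(hab)):
        raise GeometryError("input rasters must be aligned")

    valid = hab.values != HABITAT_NODATA
    if region_mask is not None:
        valid = valid & np.asarray(region_mask, dtype=bool)
    cand_iy, cand_ix = np.nonzero(valid)
    if cand_iy.size < n_points:
        raise ValueError(f"region has {cand_iy.size} samplable cells < n_points={n_points}")

    rng = np.random.default_rng(seed)
    pick = rng.choice(cand_iy.size, size=n_points, replace=False)
    iy0 = cand_iy[pick]
    ix0 = cand_ix[pick]

    layers = _fractions_stack(hab, chl, edge)
    dy, dx = disk_offsets(radius, hab.cell_size)
    ny, nx = hab.shape
    xs = hab.origin[0] + (ix0 + 0.5) * hab.cell_size
    ys = hab.origin[1] + (iy0 + 0.5) * hab.cell_size

    rows = []
    dropped = {s: 0 for s in SOURCES}
    for k in range(n_points):
        iy = iy0[k] + dy
        ix = ix0[k] + dx
        keep = (iy >= 0) & (iy < ny) & (ix >= 0) & (ix < nx)
        iy, ix = iy[keep], ix[keep]
        ok = hab.values[iy, ix] != HABITAT_NODATA
        n_valid = int(ok.sum())
        if n_valid == 0:
            for s in SOURCES:
                dropped[s] += 1
            continue
        fhab = layers[:, iy[ok], ix[ok]].sum(axis=1) / n_valid
        for si, s in enumerate(SOURCES):
            if fhab[si] > 0:
                rows.append((xs[k], ys[k], s, fhab[si], fsource[si] / fhab[si]))
            else:
                dropped[s] += 1

    points = pd.DataFrame(rows, columns=["x", "y", "source", "fhabitat", "iei"])
    summ = []
    for s in SOURCES:
        vals = points.loc[points["source"] == s, "iei"].to_numpy()
        if vals.size:
            summ.append((s, np.median(vals), np.quantile(vals, 0.25), np.quantile(vals, 0.75), vals.size))
        else:
            summ.append((s, np.nan, np.nan, np.nan, 0))
    summary = pd.DataFrame(summ, columns=["source", "median", "q25", "q75", "n_points"])
    for s, n in dropped.items():
        if n:
            logger.info("IEI calibration: %d/%d points lacked %s habitat", n, n_points, s)
    return IEITable(points=points, summary=summary, dropped=dropped, year=year)


def compute_hri(
    hab: Raster,
    chl: Raster,
    edge: Raster,
    iei: IEITable,
    unit: float = 1000.0,
    year: str | None = None,
) -> EScape:
    """Map HRI on a coarse landscape-foraging-unit grid (default 1 km).

    Units are anchored at the raster origin; partial units along the top and
    right edges use the valid cells they contain; units with no valid habitat
    cells are NaN.
    """
    cs = hab.cell_size
    uc = unit / cs
    if unit < cs or abs(uc - round(uc)) > 1e-9:
        raise ValueError("unit must be a positive whole multiple of the cell size")
    uc = int(round(uc))
    if not (chl.aligned_with(hab) and edge.aligned_with(hab)):
        raise GeometryError("input rasters must be aligned")

    ny, nx = hab.shape
    nby = int(np.ceil(ny / uc))
    nbx = int(np.ceil(nx / uc))
    pad_y, pad_x = nby * uc - ny, nbx * uc - nx

    layers = _fractions_stack(hab, chl, edge)
    valid = (hab.values != HABITAT_NODATA).astype(float)
    layers = layers * valid  # nodata cells contribute nothing
    layers = np.pad(layers, ((0, 0), (0, pad_y), (0, pad_x)))
    valid = np.pad(valid, ((0, pad_y), (0, pad_x)))

    def block_sum(a):
        return a.reshape(*a.shape[:-2], nby, uc, nbx, uc).sum(axis=(-3, -1))

    n_valid = block_sum(valid)
    sums = block_sum(layers)
    med = iei.medians()

    with np.errstate(divide="ignore", invalid="ignore"):
        frac = sums / n_valid
    hri = np.zeros((nby, nbx))
    for si in range(3):
        contrib = np.where(np.isfinite(med[si]), med[si], 0.0) * frac[si]
        hri += np.nan_to_num(contrib, nan=0.0)
    hri[n_valid == 0] = np.nan

    hri_raster = Raster(values=hri, cell_size=float(unit), origin=hab.origin)
    return EScape(hri=hri_raster, iei=iei, year=year)


def sample_hri(escape: EScape, points) -> np.ndarray:
    """HRI of the landscape unit containing each (x, y) point.

    Points outside the extent or in nodata units yield NaN (never silently
    0); the counts are logged.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    iy, ix, inside = escape.hri.cell_indices(pts[:, 0], pts[:, 1])
    out = np.full(pts.shape[0], np.nan)
    vals = np.asarray(escape.hri.values, dtype=float)
    out[inside] = vals[iy[inside], ix[inside]]
    n_outside = int((~inside).sum())
    n_nodata = int(np.isnan(out).sum()) - n_outside
    if n_outside:
        logger.warning("sample_hri: %d points outside E-scape extent", n_outside)
    if n_nodata:
        logger.info("sample_hri: %d points in nodata units", n_nodata)
    return out


class EScapeBuilder:
    """Estimator that calibrates IEI on a landscape and maps HRI.

    ``fit`` draws random calibration buffers and stores the IEI table;
    ``transform`` maps HRI on the landscape-unit grid. The input ``X`` is a
    ``(habitat, chlorophyll)`` raster pair.

    Parameters
    ----------
    fsource : array-like of 3
        Source contribution medians (phytoplankton, benthic, marsh).
    n_points : int, default 1000
        Calibration points.
    radius : float, default 500
        Buffer radius, m.
    unit : float, default 1000
        Landscape foraging unit edge, m.
    edge_width : float, default 10
        Width used to express marsh-water boundary length as area, m.
    random_state : int or None
        Calibration point sampling seed.
    """

    def __init__(
        self,
        fsource=(0.68, 0.23, 0.09),
        n_points: int = 1000,
        radius: float = 500.0,
        unit: float = 1000.0,
        edge_width: float = 10.0,
        edge_side: str = "water",
        year: str | None = None,
        random_state: int | None = None,
    ):
        self.fsource = fsource
        self.n_points = n_points
        self.radius = radius
        self.unit = unit
        self.edge_width = edge_width
        self.edge_side = edge_side
        self.year = year
        self.random_state = random_state

    # sklearn-style param plumbing (kept dependency-free)
    def get_params(self, deep: bool = True) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "fsource",
                "n_points",
                "radius",
                "unit",
                "edge_width",
                "edge_side",
                "year",
                "random_state",
            )
        }

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None):
        hab, chl = X
        self.edge_ = edge_area(hab, width=self.edge_width, side=self.edge_side)
        self.iei_table_ = compute_iei(
            hab,
            chl,
            self.edge_,
            self.fsource,
            n_points=self.n_points,
            radius=self.radius,
            seed=self.random_state,
            year=self.year,
        )
        return self

    def transform(self, X) -> EScape:
        if not hasattr(self, "iei_table_"):
            raise RuntimeError("EScapeBuilder is not fitted")
        hab, chl = X
        edge = edge_area(hab, width=self.edge_width, side=self.edge_side)
        return compute_hri(hab, chl, edge, self.iei_table_, unit=self.unit, year=self.year)

    def fit_transform(self, X, y=None) -> EScape:
        return self.fit(X).transform(X)
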