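"""Kernel utilization distributions on a 1-degree grid.

The UD is a bivariate Gaussian kernel density in unprojected (lon, lat)
degree space with smoothing parameter ``h`` (degrees, default 1.8 — roughly
a 200 km search radius at subantarctic latitudes) evaluated at the centres
of 1x1-degree cells; contours are discrete minimal superlevel cell sets
(the smallest set of cells holding the requested probability mass), so the
50% set is the core area and the 95% set the home range, with the 50% set
always nested in the 95% one.  A caveat of degree-space kernels: one degree
of longitude shrinks with latitude, so cell areas in km are not uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

__all__ = ["KernelUD", "UDContour", "kernel_ud", "ud_contour", "core_centroid"]


@dataclass
class KernelUD:
    lat_centers: np.ndarray  # ascending
    lon_centers: np.ndarray  # ascending
    density: np.ndarray  # shape (n_lat, n_lon); integrates to 1 over deg^2
    h: float
    grid: float
    n_points: int

    @property
    def cell_area(self) -> float:
        return self.grid * self.grid

    def cell_mass(self) -> np.ndarray:
        return self.density * self.cell_area


@dataclass
class UDContour:
    level: float  # percent
    cells: np.ndarray  # (k, 2) array of (lat, lon) member cell centers
    mass: float  # cumulative probability mass of the member cells
    polygon: object  # shapely (Multi)Polygon: union of member cell squares

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def kernel_ud(lats, lons, h: float = 1.8, grid: float = 1.0) -> KernelUD:
    """Gaussian kernel UD of a point set in degree space.

    The grid covers the points' bounding box padded by ``3 h``, with cell
    centres on half-grid offsets; the density is normalized so that
    sum(density) * cell_area == 1.
    """
    lats = np.atleast_1d(np.asarray(lats, float))
    lons = np.atleast_1d(np.asarray(lons, float))
    if lats.size == 0:
        raise ValueError("kernel_ud needs at least one point")
    if h <= 0 or grid <= 0:
        raise ValueError("h and grid must be > 0")
    pad = 3.0 * h

    def centers(lo, hi):
        start = np.floor((lo - pad) / grid) * grid + grid / 2.0
        return np.arange(start, hi + pad + grid / 2.0, grid)

    lat_c = centers(lats.min(), lats.max())
    lon_c = centers(lons.min(), lons.max())
    dlat = (lat_c[:, None] - lats[None, :]) / h
    dlon = (lon_c[:, None] - lons[None, :]) / h
    klat = np.exp(-0.5 * dlat**2)
    klon = np.exp(-0.5 * dlon**2)
    dens = klat @ klon.T / (2.0 * np.pi * h * h * lats.size)
    dens /= dens.sum() * grid * grid
    return KernelUD(lat_centers=lat_c, lon_centers=lon_c, density=dens, h=h, grid=grid, n_points=lats.size)


def ud_contour(ud: KernelUD, level: float) -> UDContour:
    """Minimal superlevel cell set holding ``level`` percent of the mass.

    Cells are accumulated in decreasing density order (ties broken by
    (lat, lon) lexicographic order) until the cumulative mass first reaches
    level/100; the member cells are polygonized as the union of their
    1x1 squares.
    """
    if not 0.0 < level < 100.0 + 1e-9:
        raise ValueError("level must be in (0, 100]")
    mass = ud.cell_mass()
    lat_g, lon_g = np.meshgrid(ud.lat_centers, ud.lon_centers, indexing="ij")
    flat = np.column_stack([mass.ravel(), lat_g.ravel(), lon_g.ravel()])
    order = np.lexsort((flat[:, 2], flat[:, 1], -flat[:, 0]))
    sorted_mass = flat[order, 0]
    cum = np.cumsum(sorted_mass)
    k = int(np.searchsorted(cum, level / 100.0 - 1e-12) + 1)
    k = min(k, len(cum))
    members = flat[order[:k], 1:]
    half = ud.grid / 2.0
    poly = unary_union([box(lo - half, la - half, lo + half, la + half) for la, lo in members])
    return UDContour(level=level, cells=members, mass=float(cum[k - 1]), polygon=poly)


def core_centroid(ud: KernelUD, level: float = 50.0, weighted: bool = True):
    """Centroid (lat, lon) of the core-area cells.

    Density-weighted by default (``weighted=False`` gives the plain mean of
    member cell centres); longitude is averaged on the circle so clouds
    straddling the date line average near +/-180, not near 0.
    """
    cont = ud_contour(ud, level)
    lats = cont.cells[:, 0]
    lons = cont.cells[:, 1]
    if weighted:
        ilat = np.searchsorted(ud.lat_centers, lats)
        ilon = np.searchsorted(ud.lon_centers, lons)
        w = ud.density[ilat, ilon]
    else:
        w = np.ones(len(lats))
    w = w / w.sum()
    lat = float(np.sum(w * lats))
    rad = np.deg2rad(lons)
    lon = float(np.rad2deg(np.arctan2(np.sum(w * np.sin(rad)), np.sum(w * np.cos(rad)))))
    return lat, lon
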