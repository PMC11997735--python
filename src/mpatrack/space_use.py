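"""Kernel utilization distributions, isopleth areas, and overlap grids.

Space use is summarized the way home-range analyses do: a bivariate normal
kernel density (the utilization distribution, UD) fitted separately to the
daily locations inside and outside the MPA, its 50% ("core") and 95%
("general") isopleths, their areas, and multi-species overlap counts on
10 km and 50 km management grids.

The KDE runs in an azimuthal-equidistant projection centred on the colony
so bandwidths and isopleth areas are in honest kilometres; the bandwidth is
the classical bivariate reference value href = 0.5 (sd_x + sd_y) n^(-1/6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import box
from shapely.ops import unary_union

from ._geo import AzimuthalEquidistant

#: degree-to-km padding conversion used for the grid extent
KM_PER_DEG = 111.32


class InsufficientPointsError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class UDRaster:
    """Kernel utilization distribution on a planar (km) grid.

    ``density`` integrates to 1: sum(density) * cell_area == 1.
    """

    x: np.ndarray            # cell-centre x (km), ascending
    y: np.ndarray            # cell-centre y (km), ascending
    density: np.ndarray      # (ny, nx), km^-2
    bandwidth_h: float       # km
    n_points: int
    proj: AzimuthalEquidistant

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


@dataclass
class Isopleth:
    level: float
    area_km2: float
    mass: float
    polygon: shapely.geometry.base.BaseGeometry   # planar km coords
    cell_mask: np.ndarray


@dataclass
class IsoplethSet:
    ud: UDRaster
    levels: dict[float, Isopleth]

    def area(self, level: float) -> float:
        return self.levels[level].area_km2

    def polygon_lonlat(self, level: float):
        """Isopleth polygon re-expressed in lon/lat (WGS84)."""
        geom = self.levels[level].polygon

        def back(coords):
            arr = np.asarray(coords)
            lon, lat = self.ud.proj.inverse(arr[:, 0], arr[:, 1])
            return np.column_stack([lon, lat])

        return shapely.transform(geom, back)


def partition_points(lon, lat, zone) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive inside/outside masks (boundary -> inside)."""
    from .zones import points_in_zone
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    inside = (points_in_zone(zone, lon, lat) if lon.size
              else np.zeros(0, dtype=bool))
    return inside, ~inside


def fit_ud(lon, lat, center: tuple[float, float] | None = None,
           grid_intervals: int = 150, extent_deg: float = 1.0,
           bandwidth_h: float | None = None) -> UDRaster:
    """Bivariate-normal-kernel UD over a padded bounding-box grid.

    Points are projected to an azimuthal-equidistant plane centred on
    ``center`` (default: the points' centroid); the grid spans the points'
    bounding box padded by ``extent_deg`` (converted to km) with
    ``grid_intervals`` cells per axis; ``href`` is the reference bandwidth
    unless overridden.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    n = lon.size
    if n < 5:
        raise InsufficientPointsError(f"need >= 5 points for a UD, got {n}")
    if center is None:
        center = (float(np.mean(lon)), float(np.mean(lat)))
    proj = AzimuthalEquidistant(*center)
    px, py = proj.forward(lon, lat)
    sx, sy = px.std(ddof=1), py.std(ddof=1)
    if sx == 0 and sy == 0:
        raise DegenerateGeometryError("all points coincide; UD undefined")
    h = bandwidth_h if bandwidth_h is not None else href_bandwidth(px, py)
    pad = extent_deg * KM_PER_DEG
    gx = np.linspace(px.min() - pad, px.max() + pad, grid_intervals)
    gy = np.linspace(py.min() - pad, py.max() + pad, grid_intervals)
    # separable Gaussian product kernel -> one matmul
    kx = np.exp(-0.5 * ((gx[:, None] - px[None, :]) / h) ** 2)   # (nx, n)
    ky = np.exp(-0.5 * ((gy[:, None] - py[None, :]) / h) ** 2)   # (ny, n)
    dens = (ky @ kx.T) / (n * 2 * np.pi * h * h)                  # (ny, nx)
    cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
    total = dens.sum() * cell
    if total <= 0:
        raise DegenerateGeometryError("zero total density")
    dens /= total   # renormalize mass clipped by the finite grid
    return UDRaster(gx, gy, dens, float(h), n, proj)


def href_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Classical bivariate normal reference bandwidth
    0.5 (sd_x + sd_y) n^(-1/6)."""
    n = len(x)
    return float(0.5 * (x.std(ddof=1) + y.std(ddof=1)) * n ** (-1.0 / 6.0))


def isopleths(ud: UDRaster, levels=(0.5, 0.95)) -> IsoplethSet:
    """Smallest cell sets containing each probability level.

    Cells are taken in descending density order (ties broken by flat cell
    index, deterministic) until the cumulative mass first reaches the
    level; the area is cell count x cell area and the polygon the union of
    the selected cell boxes.
    """
    out = {}
    cell = ud.cell_area
    flat = ud.density.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    cum = np.cumsum(flat[order]) * cell
    for level in levels:
        if not 0 < level < 1:
            raise ValueError("isopleth level must be in (0, 1)")
        k = int(np.searchsorted(cum, level)) + 1
        k = min(k, flat.size)
        chosen = order[:k]
        mask = np.zeros(flat.size, dtype=bool)
        mask[chosen] = True
        mask = mask.reshape(ud.density.shape)
        out[level] = Isopleth(level, float(k * cell), float(cum[k - 1]),
                              _cells_to_polygon(ud, mask), mask)
    return IsoplethSet(ud, out)


def _cells_to_polygon(ud: UDRaster, mask: np.ndarray):
    dx = ud.x[1] - ud.x[0]
    dy = ud.y[1] - ud.y[0]
    iy, ix = np.nonzero(mask)
    boxes = [box(ud.x[j] - dx / 2, ud.y[i] - dy / 2,
                 ud.x[j] + dx / 2, ud.y[i] + dy / 2)
             for i, j in zip(iy, ix)]
    return unary_union(boxes)


def area_inside_zone(iso: IsoplethSet, level: float, zone_lonlat) -> float:
    """Area (km^2) of the level-isopleth falling inside a lon/lat zone.

    The zone polygon is projected into the UD's planar frame first.
    """
    proj = iso.ud.proj

    def fwd(coords):
        arr = np.asarray(coords)
        x, y = proj.forward(arr[:, 0], arr[:, 1])
        return np.column_stack([x, y])

    zone_planar = shapely.transform(zone_lonlat, fwd)
    return float(iso.levels[level].polygon.intersection(zone_planar).area)


def species_overlap_grid(iso_sets: dict[str, IsoplethSet], level: float,
                         cell_km: float = 10.0,
                         center: tuple[float, float] | None = None):
    """Count, per ``cell_km`` x ``cell_km`` cell, how many species'
    level-isopleths intersect the cell.

    All isopleth polygons are mapped into one shared azimuthal-equidistant
    frame (centred on ``center``, default the first UD's centre) before
    counting.  Returns (x_centres, y_centres, count_grid).
    """
    if not iso_sets:
        raise ValueError("no isopleth sets supplied")
    first = next(iter(iso_sets.values()))
    if center is None:
        center = (first.ud.proj.lon0, first.ud.proj.lat0)
    proj = AzimuthalEquidistant(*center)

    polys = {}
    for name, iso in iso_sets.items():
        geo = iso.polygon_lonlat(level)

        def fwd(coords):
            arr = np.asarray(coords)
            x, y = proj.forward(arr[:, 0], arr[:, 1])
            return np.column_stack([x, y])

        polys[name] = shapely.transform(geo, fwd)

    bounds = np.array([p.bounds for p in polys.values()])
    x0, y0 = bounds[:, 0].min(), bounds[:, 1].min()
    x1, y1 = bounds[:, 2].max(), bounds[:, 3].max()
    x0 = np.floor(x0 / cell_km) * cell_km
    y0 = np.floor(y0 / cell_km) * cell_km
    nx = max(int(np.ceil((x1 - x0) / cell_km)), 1)
    ny = max(int(np.ceil((y1 - y0) / cell_km)), 1)
    xc = x0 + (np.arange(nx) + 0.5) * cell_km
    yc = y0 + (np.arange(ny) + 0.5) * cell_km
    counts = np.zeros((ny, nx), dtype=int)
    for p in polys.values():
        prepared = shapely.prepared.prep(p)
        bx0, by0, bx1, by1 = p.bounds
        j0 = max(int((bx0 - x0) // cell_km), 0)
        j1 = min(int((bx1 - x0) // cell_km) + 1, nx)
        i0 = max(int((by0 - y0) // cell_km), 0)
        i1 = min(int((by1 - y0) // cell_km) + 1, ny)
        for i in range(i0, i1):
            for j in range(j0, j1):
                cellbox = box(x0 + j * cell_km, y0 + i * cell_km,
                              x0 + (j + 1) * cell_km, y0 + (i + 1) * cell_km)
                if prepared.intersects(cellbox):
                    counts[i, j] += 1
    return xc, yc, counts
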