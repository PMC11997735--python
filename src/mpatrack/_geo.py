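"""Spherical geometry primitives.

All distance math runs on a sphere of radius 6371.0088 km (IUGG mean Earth
radius).  Longitudes are kept in [-180, 180) and unwrapped locally where
interpolation crosses the antimeridian.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def wrap_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def wrap_angle(theta):
    """Wrap angles (radians) into (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    out = -((-theta + np.pi) % (2 * np.pi) - np.pi)
    return out


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing (radians clockwise from north)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def destination_point(lon, lat, bearing_rad, distance_km):
    """Point reached travelling ``distance_km`` along ``bearing_rad`` on the sphere."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    theta = np.asarray(bearing_rad, dtype=float)
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta)
                     + np.cos(lat1) * np.sin(delta) * np.cos(theta))
    lon2 = lon1 + np.arctan2(np.sin(theta) * np.sin(delta) * np.cos(lat1),
                             np.cos(delta) - np.sin(lat1) * np.sin(lat2))
    return wrap_lon(np.degrees(lon2)), np.degrees(lat2)


def great_circle_interpolate(lon1, lat1, lon2, lat2, fractions):
    """Points along the great circle at the given fractions in [0, 1].

    Slerp on unit vectors; degenerate (coincident endpoints) returns the
    start point.
    """
    f = np.atleast_1d(np.asarray(fractions, dtype=float))
    a = lonlat_to_xyz(lon1, lat1)
    b = lonlat_to_xyz(lon2, lat2)
    omega = np.arccos(np.clip(np.dot(a, b), -1.0, 1.0))
    if omega < 1e-12:
        pts = np.repeat(a[None, :], len(f), axis=0)
    else:
        s = np.sin(omega)
        pts = (np.sin((1 - f)[:, None] * omega) * a[None, :]
               + np.sin(f[:, None] * omega) * b[None, :]) / s
    return xyz_to_lonlat(pts)


def lonlat_to_xyz(lon, lat):
    """Unit vectors for lon/lat degrees; shape (..., 3)."""
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon),
                     np.cos(lat) * np.sin(lon),
                     np.sin(lat)], axis=-1)


def xyz_to_lonlat(xyz):
    xyz = np.asarray(xyz, dtype=float)
    norm = np.linalg.norm(xyz, axis=-1, keepdims=True)
    x, y, z = np.moveaxis(xyz / norm, -1, 0)
    lat = np.degrees(np.arcsin(np.clip(z, -1.0, 1.0)))
    lon = wrap_lon(np.degrees(np.arctan2(y, x)))
    return lon, lat


class AzimuthalEquidistant:
    """Azimuthal-equidistant projection centred on (lon0, lat0).

    Distances from the centre are exact great-circle distances (km), which
    keeps kernel bandwidths and isopleth areas meaningful at the scale of
    animal home ranges.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)

    def forward(self, lon, lat):
        """lon/lat degrees -> (x, y) km."""
        d = haversine_km(self.lon0, self.lat0, lon, lat)
        az = initial_bearing_rad(self.lon0, self.lat0, lon, lat)
        return d * np.sin(az), d * np.cos(az)

    def inverse(self, x, y):
        """(x, y) km -> lon/lat degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        d = np.hypot(x, y)
        az = np.arctan2(x, y)
        lon, lat = destination_point(self.lon0, self.lat0, az, d)
        # destination_point is undefined at d == 0; patch the centre back in
        lon = np.where(d == 0, self.lon0, lon)
        lat = np.where(d == 0, self.lat0, lat)
        if np.ndim(x) == 0:
            return float(lon), float(lat)
        return lon, lat


def geodesic_median(lons, lats, tol_rad: float = 1e-10, max_iter: int = 1000):
    """Geodesic (spatial) median of points on the sphere.

    Riemannian Weiszfeld iteration: repeatedly move the estimate to the
    1/distance-weighted Karcher mean in the tangent plane.  Returns
    ``(lon, lat, converged)``.  A point coincident with the current estimate
    gets a distance floor rather than special-casing the optimality test;
    at telemetry precision this is indistinguishable from the exact rule.
    """
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    if lons.size == 1:
        return float(lons[0]), float(lats[0]), True
    p = lonlat_to_xyz(lons, lats)             # (n, 3)
    m = p.mean(axis=0)
    m /= np.linalg.norm(m)
    eps = 1e-12
    converged = False
    for _ in range(max_iter):
        cosd = np.clip(p @ m, -1.0, 1.0)
        d = np.arccos(cosd)                    # angular distances
        w = 1.0 / np.maximum(d, eps)
        # log map of each point at m
        perp = p - cosd[:, None] * m[None, :]
        nrm = np.linalg.norm(perp, axis=1)
        ok = nrm > eps
        logs = np.zeros_like(p)
        logs[ok] = perp[ok] * (d[ok] / nrm[ok])[:, None]
        step = (w[:, None] * logs).sum(axis=0) / w.sum()
        step_norm = np.linalg.norm(step)
        if step_norm < tol_rad:
            converged = True
            break
        # exp map
        m = np.cos(step_norm) * m + np.sin(step_norm) * step / step_norm
        m /= np.linalg.norm(m)
    lon, lat = xyz_to_lonlat(m)
    if not converged:
        # fall back to the best candidate among the inputs
        totals = [np.sum(np.arccos(np.clip(p @ p[i], -1, 1))) for i in range(len(p))]
        best = np.sum(np.arccos(np.clip(p @ m, -1, 1)))
        i = int(np.argmin(totals))
        if totals[i] < best:
            return float(lons[i]), float(lats[i]), False
    return float(lon), float(lat), converged
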