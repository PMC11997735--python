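"""Pseudo-absence generation and presence/absence table assembly.

True absences are unobservable in telemetry, so habitat models contrast
observed presences with pseudo-absences generated two ways:

* **background** — uniform points within the individual's maximum track
  extent (its lon/lat bounding box);
* **CRW** — correlated random walks that resample the observed track's
  empirical step-length and turning-angle distributions, start at the
  observed start point, and take the same number of steps.

One hundred simulations are generated per individual; one is drawn at
random and date-matched 1:1 to the presence days.  The Bhattacharyya
coefficient quantifies how environmentally distinct presences and
pseudo-absences are.  Both a daily (median-location) and an
original-resolution pathway exist; tables carry a ``resolution`` tag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._geo import (destination_point, haversine_km, initial_bearing_rad,
                   wrap_angle, wrap_lon)

N_SIMULATIONS = 100


class NotEnoughStepsError(ValueError):
    """Track too short (< 3 points) to estimate step distributions."""


@dataclass
class Extent:
    """Dateline-aware lon/lat bounding box."""

    lon_min: float
    lon_max: float   # may exceed 180 when the box crosses the antimeridian
    lat_min: float
    lat_max: float

    def contains(self, lon, lat) -> np.ndarray:
        lon = np.asarray(lon, dtype=float)
        lo = np.where(lon < self.lon_min, lon + 360.0, lon)
        return ((lo >= self.lon_min) & (lo <= self.lon_max)
                & (np.asarray(lat) >= self.lat_min)
                & (np.asarray(lat) <= self.lat_max))


@dataclass
class StepDistribution:
    """Empirical multisets of step lengths (km) and turning angles (rad,
    wrapped to (-pi, pi]) from one observed track."""

    lengths_km: np.ndarray
    turn_angles: np.ndarray

    def __post_init__(self):
        if (self.lengths_km < 0).any():
            raise ValueError("negative step length")
        if (np.abs(self.turn_angles) > np.pi + 1e-12).any():
            raise ValueError("turning angle outside (-pi, pi]")


def track_extent(lon, lat) -> Extent:
    """Tight bounding box of the points, unwrapped across the dateline when
    the raw span exceeds 180 degrees."""
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size == 0:
        raise ValueError("extent of an empty point set")
    if lon.max() - lon.min() > 180.0:
        lon = np.where(lon < 0, lon + 360.0, lon)
    return Extent(float(lon.min()), float(lon.max()),
                  float(lat.min()), float(lat.max()))


def background_sample(extent: Extent, n: int, seed: int | np.random.Generator = 0,
                      jitter_deg: float = 0.25) -> pd.DataFrame:
    """``n`` uniform points inside the extent (seeded, reproducible).

    A degenerate (zero-width) extent is jittered by one covariate-grid cell
    so sampling stays well defined.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lo0, lo1 = extent.lon_min, extent.lon_max
    la0, la1 = extent.lat_min, extent.lat_max
    if lo1 - lo0 == 0 or la1 - la0 == 0:
        import warnings
        warnings.warn("degenerate extent; jittering by one grid cell")
        lo0, lo1 = lo0 - jitter_deg / 2, lo1 + jitter_deg / 2
        la0, la1 = la0 - jitter_deg / 2, la1 + jitter_deg / 2
    lon = wrap_lon(rng.uniform(lo0, lo1, n))
    lat = rng.uniform(la0, la1, n)
    return pd.DataFrame({"lon": lon, "lat": lat})


def step_distribution(lon, lat) -> StepDistribution:
    """Empirical step lengths and relative turning angles of a track.

    "Inter-point angles" are read as relative turning angles (the standard
    CRW construction): the change in great-circle bearing between
    consecutive steps.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    if lon.size < 3:
        raise NotEnoughStepsError("need >= 3 points for step distributions")
    lengths = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    bearings = initial_bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
    turns = wrap_angle(np.diff(bearings))
    return StepDistribution(lengths, turns)


def crw_simulate(lon, lat, n_sims: int = N_SIMULATIONS,
                 seed: int | np.random.Generator = 0) -> list[pd.DataFrame]:
    """Correlated-random-walk null tracks for one observed track.

    Each simulation starts at the observed start point with a uniform first
    heading, then resamples step lengths and turning angles independently
    with replacement, producing a track with the same number of points.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    dist = step_distribution(lon, lat)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_steps = lon.size - 1
    sims = []
    for _ in range(n_sims):
        L = rng.choice(dist.lengths_km, size=n_steps, replace=True)
        T = rng.choice(dist.turn_angles, size=n_steps, replace=True)
        heading = rng.uniform(-np.pi, np.pi)
        slon = np.empty(lon.size)
        slat = np.empty(lat.size)
        slon[0], slat[0] = lon[0], lat[0]
        for i in range(n_steps):
            if i > 0:
                heading = wrap_angle(heading + T[i])
            slon[i + 1], slat[i + 1] = destination_point(slon[i], slat[i],
                                                         heading, L[i])
        sims.append(pd.DataFrame({"lon": slon, "lat": slat}))
    return sims


def assemble(presences: pd.DataFrame, sim_pool: list[pd.DataFrame],
             mode: str, seed: int | np.random.Generator = 0,
             resolution: str = "daily") -> pd.DataFrame:
    """Label presences 1 and one randomly chosen simulation 0, 1:1.

    ``presences`` needs columns (individual_id, local_day, lon, lat).  The
    k-th simulated point is date-matched to the k-th presence day, which
    preserves the temporal pairing the covariate-annotation step relies
    on.  Simulations longer than the presence set are truncated; shorter
    ones are recycled from their start.
    """
    if mode not in ("background", "crw"):
        raise ValueError("mode must be 'background' or 'crw'")
    if not sim_pool:
        raise ValueError("empty simulation pool")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pres = presences.reset_index(drop=True)
    n = len(pres)
    sim = sim_pool[int(rng.integers(len(sim_pool)))].reset_index(drop=True)
    idx = np.arange(n) % len(sim)
    absent = pd.DataFrame({
        "individual_id": pres["individual_id"].values,
        "local_day": pres["local_day"].values,
        "lon": sim["lon"].values[idx],
        "lat": sim["lat"].values[idx],
    })
    pres_rows = pres[["individual_id", "local_day", "lon", "lat"]].copy()
    pres_rows["label"] = 1
    pres_rows["source"] = "observed"
    absent["label"] = 0
    absent["source"] = mode
    out = pd.concat([pres_rows, absent], ignore_index=True)
    out["resolution"] = resolution
    return out


def default_n_bins(n_p: int, n_q: int) -> int:
    """Histogram bin heuristic: ceil(sqrt(min(n))), clipped to [5, 50]."""
    return int(np.clip(np.ceil(np.sqrt(min(n_p, n_q))), 5, 50))


def bhattacharyya(sample_p, sample_q, n_bins: int | None = None) -> float:
    """Bhattacharyya coefficient between two samples of one covariate.

    BC = sum_i sqrt(p_i q_i) over shared equal-width bins spanning the
    pooled range; 1 for identical distributions, 0 for disjoint supports.
    A zero pooled range (both samples a single identical value) returns 1.
    """
    p = np.asarray(sample_p, dtype=float)
    q = np.asarray(sample_q, dtype=float)
    p = p[np.isfinite(p)]
    q = q[np.isfinite(q)]
    if p.size == 0 or q.size == 0:
        raise ValueError("both samples must be non-empty")
    lo = min(p.min(), q.min())
    hi = max(p.max(), q.max())
    if hi == lo:
        return 1.0
    if n_bins is None:
        n_bins = default_n_bins(p.size, q.size)
    edges = np.linspace(lo, hi, n_bins + 1)
    hp, _ = np.histogram(p, bins=edges)
    hq, _ = np.histogram(q, bins=edges)
    return float(np.sqrt((hp / hp.sum()) * (hq / hq.sum())).sum())


def bhattacharyya_table(table: pd.DataFrame, covariates,
                        n_bins: int | None = None) -> pd.Series:
    """Per-covariate BC between presence and pseudo-absence rows."""
    pres = table[table["label"] == 1]
    absn = table[table["label"] == 0]
    return pd.Series({c: bhattacharyya(pres[c], absn[c], n_bins)
                      for c in covariates if c in table})
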