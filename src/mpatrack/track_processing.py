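"""Clean, filter, regularize, and reduce raw telemetry to daily locations.

The processing chain mirrors standard multi-tag telemetry practice:

1. trim to the deployment window;
2. species-specific iterative speed filter (great-circle speeds);
3. removal of nest-centred points within a radius of the colony
   (central-place foragers only);
4. central-place foraging-trip segmentation;
5. time-regularization by vmax-gated great-circle interpolation;
6. reduction to one geodesic-median location per individual per local day
   (HST, UTC-10, no daylight saving), the common currency for kernel
   density estimation and habitat models across tag types whose native
   resolutions span 2 min to 12 h.

All operations preserve time order and are idempotent on conforming input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._geo import (geodesic_median, great_circle_interpolate, haversine_km)
from .zones import points_in_zone

#: longer gaps are never interpolated across; segments on either side keep
#: the same individual identity but regularization restarts after the gap
DEFAULT_GAP_MAX_DAYS = 20.0
#: Hawaii Standard Time, the local day used for daily medians
HST_UTC_OFFSET_HOURS = -10.0

TRACK_COLUMNS = ["timestamp", "lon", "lat"]


@dataclass
class RawTrack:
    """One individual's locations: tz-aware UTC timestamps, lon/lat degrees.

    ``data`` columns: timestamp, lon, lat, optionally depth_m (metres,
    positive down).  Timestamps strictly increasing.
    """

    data: pd.DataFrame
    individual_id: str
    species: str
    tag_type: str = ""

    def __post_init__(self):
        d = self.data.reset_index(drop=True)
        if len(d):
            ts = pd.to_datetime(d["timestamp"], utc=True)
            if ts.duplicated().any():
                raise ValueError("duplicate timestamps")
            if not ts.is_monotonic_increasing:
                raise ValueError("timestamps must be strictly increasing")
            d = d.assign(timestamp=ts)
            if not (np.isfinite(d["lon"]).all() and np.isfinite(d["lat"]).all()):
                raise ValueError("non-finite coordinates")
        self.data = d

    def __len__(self) -> int:
        return len(self.data)

    def with_data(self, d: pd.DataFrame) -> "RawTrack":
        return replace(self, data=d.reset_index(drop=True))


@dataclass
class RegularTrack(RawTrack):
    """Time-regular track: constant ``dt`` seconds between consecutive fixes
    within a segment (the ``segment`` column separates gap-split pieces)."""

    dt: float = 0.0


@dataclass
class Trip:
    """One central-place foraging trip."""

    individual_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    indices: np.ndarray
    max_distance_km: float

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


@dataclass
class DailyTrack:
    """One geodesic-median location per individual per local (HST) day.

    ``data`` columns: local_day (date), lon, lat, n_fixes, converged, and —
    after :func:`flag_zones` — one ``inside_<zone>`` bool column per zone.
    """

    data: pd.DataFrame
    individual_id: str
    species: str

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# cleaning

def trim_to_deployment(track: RawTrack, start, end) -> RawTrack:
    """Keep fixes within [start, end] inclusive."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")
    if end.tzinfo is None:
        end = end.tz_localize("UTC")
    if not start < end:
        raise ValueError("deployment start must precede end")
    ts = track.data["timestamp"]
    out = track.with_data(track.data[(ts >= start) & (ts <= end)])
    if len(out) == 0:
        warnings.warn(f"{track.individual_id}: no fixes in deployment window")
    return out


def speed_filter(track: RawTrack, vmax: float) -> RawTrack:
    """Iteratively drop fixes arriving faster than ``vmax`` (m/s).

    The first fix is always retained; each subsequent fix is tested against
    the previous *retained* fix, so an isolated teleporting outlier is
    removed without discarding the good fixes around it.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    d = track.data
    if len(d) < 2:
        return track
    ts = d["timestamp"].values.astype("datetime64[ns]").astype("int64") / 1e9
    lon, lat = d["lon"].values, d["lat"].values
    keep = [0]
    for i in range(1, len(d)):
        j = keep[-1]
        dt = ts[i] - ts[j]
        v = haversine_km(lon[j], lat[j], lon[i], lat[i]) * 1000.0 / dt
        if v <= vmax:
            keep.append(i)
    if len(keep) == 1:
        warnings.warn(f"{track.individual_id}: speed filter left a single fix")
    return track.with_data(d.iloc[keep])


def remove_colony_points(track: RawTrack, center: tuple[float, float],
                         radius_km: float = 5.0) -> RawTrack:
    """Drop fixes strictly within ``radius_km`` of the colony/central place."""
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    d = track.data
    dist = haversine_km(center[0], center[1], d["lon"].values, d["lat"].values)
    return track.with_data(d[dist >= radius_km])


def segment_trips(track: RawTrack, center: tuple[float, float],
                  dist_km: float = 5.0, min_duration_h: float = 1.0) -> list[Trip]:
    """Maximal runs of fixes strictly beyond ``dist_km`` of the central
    place, kept when the run lasts at least ``min_duration_h``."""
    d = track.data
    if len(d) == 0:
        return []
    dist = haversine_km(center[0], center[1], d["lon"].values, d["lat"].values)
    away = dist > dist_km
    trips: list[Trip] = []
    i = 0
    n = len(d)
    while i < n:
        if not away[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and away[j + 1]:
            j += 1
        start = d["timestamp"].iloc[i]
        end = d["timestamp"].iloc[j]
        if (end - start) >= pd.Timedelta(hours=min_duration_h):
            trips.append(Trip(track.individual_id, start, end,
                              np.arange(i, j + 1), float(dist[i:j + 1].max())))
        i = j + 1
    return trips


# ---------------------------------------------------------------------------
# regularization

def regularize(track: RawTrack, dt: float, vmax: float | None = None,
               gap_max_days: float = DEFAULT_GAP_MAX_DAYS) -> RegularTrack:
    """Resample to fixes evenly spaced ``dt`` seconds apart.

    Positions are great-circle interpolations between the bracketing raw
    fixes.  Raw gaps longer than ``gap_max_days`` are never interpolated
    across: the track is split into segments (numbered in the ``segment``
    column) that restart the regular clock, while remaining one track for
    identity purposes.  Because each interpolated point lies on the chord of
    a raw segment, implied speeds never exceed the raw segment speed, so a
    speed-filtered input keeps ``speed <= vmax``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    d = track.data
    if len(d) < 2:
        raise ValueError("need at least 2 fixes to regularize")
    ts = d["timestamp"].values.astype("datetime64[ns]").astype("int64") / 1e9
    med = float(np.median(np.diff(ts)))
    if dt < med / 10:
        warnings.warn(f"dt={dt}s oversamples the raw track (median interval {med:.0f}s)")
    lon, lat = d["lon"].values, d["lat"].values
    gap_s = gap_max_days * 86400.0
    # split raw track at long gaps
    breaks = np.flatnonzero(np.diff(ts) > gap_s)
    seg_bounds = np.split(np.arange(len(d)), breaks + 1)
    rows = []
    for seg_no, idx in enumerate(seg_bounds):
        if len(idx) < 2:
            continue
        t0, t1 = ts[idx[0]], ts[idx[-1]]
        n_t = int((t1 - t0) / dt + 1e-6) + 1
        t_targets = t0 + dt * np.arange(n_t)
        j = idx[0]
        for t in t_targets:
            while j + 1 <= idx[-1] and ts[j + 1] <= t:
                j += 1
            if j >= idx[-1]:
                jlo, jhi = idx[-1] - 1, idx[-1]
            else:
                jlo, jhi = j, j + 1
            span = ts[jhi] - ts[jlo]
            f = 0.0 if span == 0 else np.clip((t - ts[jlo]) / span, 0.0, 1.0)
            plon, plat = great_circle_interpolate(lon[jlo], lat[jlo],
                                                  lon[jhi], lat[jhi], [f])
            rows.append((pd.Timestamp(t, unit="s", tz="UTC"),
                         float(plon[0]), float(plat[0]), seg_no))
    out = pd.DataFrame(rows, columns=["timestamp", "lon", "lat", "segment"])
    return RegularTrack(out, track.individual_id, track.species,
                        track.tag_type, dt=dt)


# ---------------------------------------------------------------------------
# daily reduction

def local_day(timestamps, tz_offset_hours: float = HST_UTC_OFFSET_HOURS):
    """Calendar date of each UTC timestamp in the fixed local zone."""
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True))
    return (ts + pd.Timedelta(hours=tz_offset_hours)).date


def daily_geodesic_median(track: RawTrack,
                          tz_offset_hours: float = HST_UTC_OFFSET_HOURS,
                          tol_rad: float = 1e-10,
                          max_iter: int = 1000) -> DailyTrack:
    """One geodesic-median location per local day.

    The daily location minimizes the sum of great-circle distances to the
    day's fixes (spherical Weiszfeld iteration).  Non-convergence falls back
    to the best raw fix and is flagged in the ``converged`` column.
    """
    d = track.data
    if len(d) == 0:
        return DailyTrack(pd.DataFrame(columns=["local_day", "lon", "lat",
                                                "n_fixes", "converged"]),
                          track.individual_id, track.species)
    days = local_day(d["timestamp"], tz_offset_hours)
    rows = []
    for day, grp in d.groupby(days, sort=True):
        lon, lat, ok = geodesic_median(grp["lon"].values, grp["lat"].values,
                                       tol_rad=tol_rad, max_iter=max_iter)
        row = {"local_day": day, "lon": lon, "lat": lat,
               "n_fixes": len(grp), "converged": ok}
        if "depth_m" in grp and grp["depth_m"].notna().any():
            row["max_depth_m"] = float(grp["depth_m"].max())
        rows.append(row)
    return DailyTrack(pd.DataFrame(rows), track.individual_id, track.species)


def summarize_depths(track: RawTrack,
                     tz_offset_hours: float = HST_UTC_OFFSET_HOURS) -> dict | None:
    """Mean ± SD of daily maximum depth, plus the overall maximum.

    Returns None when the track has no depth channel.
    """
    d = track.data
    if "depth_m" not in d or d["depth_m"].notna().sum() == 0:
        return None
    sub = d[d["depth_m"].notna()]
    days = local_day(sub["timestamp"], tz_offset_hours)
    daily_max = sub.groupby(days)["depth_m"].max()
    return {"mean_daily_max_m": float(daily_max.mean()),
            "sd_daily_max_m": float(daily_max.std(ddof=1)) if len(daily_max) > 1 else 0.0,
            "max_depth_m": float(daily_max.max()),
            "n_days": int(len(daily_max))}


# ---------------------------------------------------------------------------
# zone accounting

def flag_zones(daily: DailyTrack, zones) -> DailyTrack:
    """Add ``inside_<zone>`` boolean columns (boundary counts inside)."""
    d = daily.data.copy()
    for name in zones.names():
        if len(d):
            d[f"inside_{name}"] = zones.contains_points(name, d["lon"].values,
                                                        d["lat"].values)
        else:
            d[f"inside_{name}"] = pd.Series(dtype=bool)
    return DailyTrack(d, daily.individual_id, daily.species)


def percent_inside(daily: DailyTrack, zone) -> float:
    """Share of daily locations inside ``zone`` (shapely polygon);
    boundary counts as inside."""
    d = daily.data
    if len(d) == 0:
        raise ValueError("percent_inside undefined for an empty daily track")
    inside = points_in_zone(zone, d["lon"].values, d["lat"].values)
    return float(inside.mean())


def percent_inside_by_individual(dailies: list[DailyTrack], zone) -> pd.Series:
    """Per-individual fraction inside ``zone`` (the default aggregation:
    mean ± SD across individuals is taken downstream)."""
    vals = {t.individual_id: percent_inside(t, zone) for t in dailies if len(t)}
    return pd.Series(vals, name="fraction_inside")


# ---------------------------------------------------------------------------
# I/O

def tracks_to_csv(tracks: list[RawTrack], path: str | Path) -> None:
    frames = []
    for t in tracks:
        d = t.data.copy()
        d.insert(0, "id", t.individual_id)
        d.insert(1, "species", t.species)
        frames.append(d)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tracks_from_csv(path: str | Path) -> list[RawTrack]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (iid, sp), grp in df.groupby(["id", "species"], sort=False):
        cols = [c for c in ("timestamp", "lon", "lat", "depth_m") if c in grp]
        out.append(RawTrack(grp[cols].reset_index(drop=True), str(iid), str(sp)))
    return out
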