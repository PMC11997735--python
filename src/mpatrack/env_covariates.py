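"""Environmental covariate stacks, point annotation, and climatologies.

An :class:`EnvStack` bundles monthly gridded surface fields (SST, chlorophyll-a,
dissolved surface oxygen, the u/v current components) with static bathymetry,
mirroring the level-4 reprocessed ocean products a habitat model would be
driven by.  Current speed and heading are derived cellwise; covariates are
appended to presence/absence points by nearest-cell lookup in the month
containing each point's date, and standardized (centred/scaled) with
parameters stored at fit time so prediction reuses them unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

#: dynamic surface fields carried by every stack (monthly layers)
DYNAMIC_VARS = ("sst", "chl", "do", "u", "v")
#: derived from u/v
DERIVED_VARS = ("speed", "heading")
#: static fields (single layer)
STATIC_VARS = ("bathy",)
#: everything a model may use, in canonical order
ALL_COVARIATES = DYNAMIC_VARS + DERIVED_VARS + STATIC_VARS


class SchemaError(KeyError):
    """Raised when a covariate name does not belong to the stack schema."""


def derive_currents(u, v):
    """Current speed sqrt(u^2+v^2) and heading atan2(v, u) (radians).

    NaN propagates; (0, 0) gives speed 0 and heading 0 by the atan2
    convention.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("u and v must have the same shape")
    return np.hypot(u, v), np.arctan2(v, u)


@dataclass
class EnvStack:
    """Monthly covariate fields plus static bathymetry on a lon/lat grid.

    Wraps an :class:`xarray.Dataset` with dims ``(time, lat, lon)`` for the
    dynamic variables and ``(lat, lon)`` for bathymetry.  ``speed`` and
    ``heading`` are derived on construction if absent.
    """

    ds: xr.Dataset

    def __post_init__(self):
        missing = [v for v in DYNAMIC_VARS + STATIC_VARS if v not in self.ds]
        if missing:
            raise SchemaError(f"stack missing variables: {missing}")
        if "speed" not in self.ds or "heading" not in self.ds:
            spd, hdg = derive_currents(self.ds["u"].values, self.ds["v"].values)
            self.ds["speed"] = (self.ds["u"].dims, spd)
            self.ds["heading"] = (self.ds["u"].dims, hdg)

    # -- basic accessors -------------------------------------------------
    @property
    def lon(self) -> np.ndarray:
        return self.ds["lon"].values

    @property
    def lat(self) -> np.ndarray:
        return self.ds["lat"].values

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.ds["time"].values)

    @property
    def is_climatology(self) -> bool:
        return bool(self.ds.attrs.get("climatology", 0))

    def covariate_names(self) -> tuple[str, ...]:
        return ALL_COVARIATES

    def layer(self, var: str, time_idx: int | None = None) -> np.ndarray:
        if var not in ALL_COVARIATES:
            raise SchemaError(f"unknown covariate {var!r}")
        da = self.ds[var]
        if "time" in da.dims:
            return da.isel(time=time_idx if time_idx is not None else 0).values
        return da.values

    # -- time matching ---------------------------------------------------
    def time_index_for(self, when) -> int | None:
        """Index of the monthly layer containing ``when``.

        Exact year-month match first; climatology stacks (and stacks asked
        for a year they do not cover) fall back to calendar-month matching.
        Returns None when no layer matches.
        """
        ts = pd.Timestamp(when)
        periods = self.times.to_period("M")
        hit = np.flatnonzero(periods == ts.to_period("M"))
        if hit.size:
            return int(hit[0])
        hit = np.flatnonzero(self.times.month == ts.month)
        if hit.size:
            return int(hit[0])
        return None

    def nearest_cell(self, lon, lat) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Nearest grid-cell indices (iy, ix) and an out-of-bounds mask.

        Per-axis nearest centre; exact midpoints resolve to the lower index
        (documented tie-break).  Points beyond half a cell outside the edge
        centres are flagged out of bounds.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ix = _nearest_index(self.lon, lon)
        iy = _nearest_index(self.lat, lat)
        dx = np.median(np.diff(self.lon)) if self.lon.size > 1 else np.inf
        dy = np.median(np.diff(self.lat)) if self.lat.size > 1 else np.inf
        oob = ((lon < self.lon[0] - dx / 2) | (lon > self.lon[-1] + dx / 2)
               | (lat < self.lat[0] - dy / 2) | (lat > self.lat[-1] + dy / 2))
        return iy, ix, oob

    # -- I/O -------------------------------------------------------------
    def to_netcdf(self, path: str | Path) -> None:
        ds = self.ds.copy()
        ds.to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "EnvStack":
        return cls(xr.load_dataset(path, engine="scipy"))


def _nearest_index(centers: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Nearest index on a sorted 1-D axis, midpoint ties to the lower index."""
    j = np.searchsorted(centers, x)
    j = np.clip(j, 1, len(centers) - 1)
    left, right = centers[j - 1], centers[j]
    choose_left = (x - left) <= (right - x)   # tie -> lower index
    idx = np.where(choose_left, j - 1, j)
    return np.clip(idx, 0, len(centers) - 1)


def annotate(points: pd.DataFrame, stack: EnvStack,
             date_col: str = "local_day") -> pd.DataFrame:
    """Append covariates to point rows by nearest-cell, month-of-date lookup.

    ``points`` must carry ``lon``, ``lat`` and a date column.  Every row gets
    either a full covariate vector or NaNs with ``covariate_missing=True``
    (point outside the grid, or date outside the stack's calendar); rows are
    never dropped here.
    """
    out = points.reset_index(drop=True).copy()
    n = len(out)
    iy, ix, oob = stack.nearest_cell(out["lon"].values, out["lat"].values)
    dates = pd.to_datetime(out[date_col])
    cols = {v: np.full(n, np.nan) for v in ALL_COVARIATES}
    missing = oob.copy()
    tidx = np.full(n, -1)
    for i, ts in enumerate(dates):
        k = stack.time_index_for(ts)
        if k is None:
            missing[i] = True
        else:
            tidx[i] = k
    for v in ALL_COVARIATES:
        da = stack.ds[v]
        if "time" in da.dims:
            arr = da.values
            ok = ~missing
            cols[v][ok] = arr[tidx[ok], iy[ok], ix[ok]]
        else:
            arr = da.values
            ok = ~oob
            cols[v][ok] = arr[iy[ok], ix[ok]]
    for v in ALL_COVARIATES:
        out[v] = cols[v]
    out["covariate_missing"] = missing
    return out


@dataclass
class ScalingParams:
    """Per-covariate centring/scaling constants computed on the fitting table."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def covariates(self) -> list[str]:
        return list(self.mean)


def standardize(table: pd.DataFrame, params: ScalingParams | None = None,
                covariates: tuple[str, ...] = ALL_COVARIATES,
                ) -> tuple[pd.DataFrame, ScalingParams]:
    """Centre and scale covariate columns to zero mean, unit SD.

    When ``params`` is given (prediction time) its constants are applied
    unchanged.  Constant columns are dropped with a warning — they cannot
    enter a model.
    """
    out = table.copy()
    if params is None:
        params = ScalingParams()
        for c in covariates:
            if c not in out:
                continue
            x = out[c].astype(float)
            sd = float(x.std(ddof=0))
            if not np.isfinite(sd) or sd == 0:
                warnings.warn(f"covariate {c!r} has zero variance; dropped")
                out = out.drop(columns=[c])
                continue
            params.mean[c] = float(x.mean())
            params.sd[c] = sd
            out[c] = (x - params.mean[c]) / sd
    else:
        for c in params.covariates():
            if c in out:
                out[c] = (out[c].astype(float) - params.mean[c]) / params.sd[c]
    return out, params


def monthly_median_composite(stacks: list[EnvStack],
                             year_range: tuple[int, int]) -> EnvStack:
    """Two-stage per-month-per-cell median climatology.

    Stage 1: within each source stack, subset to the year range and take the
    median per calendar month per cell.  Stage 2: median across source
    stacks.  Bathymetry is medianed across stacks directly.  The result is a
    12-layer climatology (nominal timestamps in the first year of the range)
    flagged so annotation matches by calendar month.
    """
    if not stacks:
        raise ValueError("need at least one source stack")
    y0, y1 = year_range
    per_stack = []
    for st in stacks:
        sel = st.ds.sel(time=(st.times.year >= y0) & (st.times.year <= y1))
        if sel.sizes.get("time", 0) == 0:
            raise ValueError(f"stack has no data in {y0}-{y1}")
        months_present = set(pd.DatetimeIndex(sel["time"].values).month)
        if months_present != set(range(1, 13)) and len(months_present) < 12:
            missing = sorted(set(range(1, 13)) - months_present)
            raise ValueError(f"months with no data in {y0}-{y1}: {missing}")
        clim = sel[list(DYNAMIC_VARS)].groupby("time.month").median("time")
        per_stack.append(clim)
    stacked = xr.concat(per_stack, dim="dataset")
    merged = stacked.median("dataset")
    bathy = xr.concat([st.ds["bathy"] for st in stacks], dim="dataset").median("dataset")
    times = pd.to_datetime([f"{y0}-{m:02d}-01" for m in merged["month"].values])
    ds = merged.rename({"month": "time"}).assign_coords(time=times)
    ds["bathy"] = bathy
    ds.attrs["climatology"] = 1
    ds.attrs["year_range"] = f"{y0}-{y1}"
    return EnvStack(ds)
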