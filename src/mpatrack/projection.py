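"""Habitat-suitability prediction over grids and climate-scenario deltas.

A fitted habitat model is scored over an environmental stack's grid
(covariates standardized with the model's stored fitting parameters —
future fields are never re-standardized), summarized against MPA/EEZ
polygons with the >= 0.67 "highly suitable" threshold, averaged across
species, and differenced between future-scenario and historical stacks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .env_covariates import EnvStack, standardize
from .sdm import SDMModel
from .zones import points_in_zone

#: suitability at or above this is "highly suitable habitat"
HIGH_SUITABILITY = 0.67


@dataclass
class SuitabilityRaster:
    """Per-cell predicted occurrence probability for one species/date."""

    da: xr.DataArray          # dims (lat, lon), values in [0, 1] or NaN
    species: str
    label: str = ""           # date or scenario/decade tag

    @property
    def lon(self) -> np.ndarray:
        return self.da["lon"].values

    @property
    def lat(self) -> np.ndarray:
        return self.da["lat"].values

    def to_netcdf(self, path) -> None:
        self.da.to_dataset(name="suitability").assign_attrs(
            species=self.species, label=self.label).to_netcdf(path, engine="scipy")


@dataclass
class ScenarioDelta:
    """Cellwise future - historical suitability for one species/scenario."""

    da: xr.DataArray
    species: str
    scenario: str
    decade: str = ""


class MissingLayerError(KeyError):
    pass


def _grid_table(stack: EnvStack, month) -> pd.DataFrame:
    """One row per grid cell with raw covariates for the given month."""
    ti = stack.time_index_for(month) if not isinstance(month, int) else month
    if ti is None:
        raise MissingLayerError(f"stack has no layer for {month!r}")
    lon2, lat2 = np.meshgrid(stack.lon, stack.lat)
    cols = {"lon": lon2.ravel(), "lat": lat2.ravel()}
    for v in stack.covariate_names():
        try:
            cols[v] = stack.layer(v, ti).ravel()
        except KeyError as e:
            raise MissingLayerError(str(e)) from e
    return pd.DataFrame(cols)


def predict_grid(model: SDMModel, stack: EnvStack, month,
                 label: str = "") -> SuitabilityRaster:
    """Score the model over every cell of the stack for one month.

    Covariates are sampled per cell, standardized with the model's stored
    scaling parameters, and scored; cells with any missing covariate come
    back NaN and stay excluded from all summaries.
    """
    if model.scaling is None:
        raise ValueError("model has no stored scaling parameters")
    tab = _grid_table(stack, month)
    std, _ = standardize(tab, params=model.scaling)
    missing_cov = [c for c in model.covariates if c not in std]
    if missing_cov:
        raise MissingLayerError(f"stack lacks covariates {missing_cov}")
    X = std[model.covariates].values
    ok = np.isfinite(X).all(axis=1)
    pred = np.full(len(tab), np.nan)
    if ok.any():
        pred[ok] = model.predict(X[ok])
    ny, nx = len(stack.lat), len(stack.lon)
    da = xr.DataArray(pred.reshape(ny, nx),
                      coords={"lat": stack.lat, "lon": stack.lon},
                      dims=("lat", "lon"))
    return SuitabilityRaster(da, model.species, label or str(month))


def summarize_zone(raster: SuitabilityRaster, zone,
                   threshold: float = HIGH_SUITABILITY) -> dict:
    """Median suitability and % of cells at/above the threshold in a zone.

    Cell membership is by cell-centre containment (boundary inside); the
    threshold is inclusive (>=).
    """
    lon2, lat2 = np.meshgrid(raster.lon, raster.lat)
    inside = points_in_zone(zone, lon2.ravel(), lat2.ravel())
    vals = raster.da.values.ravel()[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("zone overlaps no data cells")
    return {"median_suitability": float(np.median(vals)),
            "pct_high": float(100.0 * np.mean(vals >= threshold)),
            "n_cells": int(vals.size)}


def multispecies_mean(rasters: list[SuitabilityRaster],
                      label: str = "mean") -> SuitabilityRaster:
    """Cellwise mean suitability across species (NaNs excluded pairwise)."""
    if not rasters:
        raise ValueError("no rasters to average")
    _check_shared_grid(rasters)
    stack = np.stack([r.da.values for r in rasters])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    da = xr.DataArray(mean, coords=rasters[0].da.coords, dims=("lat", "lon"))
    return SuitabilityRaster(da, species="all", label=label)


def count_high_species(rasters: list[SuitabilityRaster],
                       threshold: float = HIGH_SUITABILITY) -> xr.DataArray:
    """Per cell, the number of species at/above the suitability threshold."""
    if not rasters:
        raise ValueError("no rasters to count")
    _check_shared_grid(rasters)
    stack = np.stack([r.da.values for r in rasters])
    counts = np.nansum(stack >= threshold, axis=0).astype(int)
    return xr.DataArray(counts, coords=rasters[0].da.coords, dims=("lat", "lon"))


def scenario_delta(model_hist: SDMModel, stack_hist: EnvStack,
                   stack_future: EnvStack, scenario: str = "",
                   decade: str = "", months=None) -> ScenarioDelta:
    """Future-minus-historical suitability under the historical model.

    The historically trained model scores both stacks (same stored
    scaling); the delta is computed per month over ``months`` (default: all
    months of the historical stack) and then annual-meaned.  Exactly
    antisymmetric under swapping the two stacks.
    """
    if (len(stack_hist.lon) != len(stack_future.lon)
            or len(stack_hist.lat) != len(stack_future.lat)
            or not np.allclose(stack_hist.lon, stack_future.lon)
            or not np.allclose(stack_hist.lat, stack_future.lat)):
        raise ValueError("historical and future stacks must share a grid")
    if months is None:
        months = list(range(len(stack_hist.times)))
    deltas = []
    for m in months:
        ph = predict_grid(model_hist, stack_hist, m).da
        pf = predict_grid(model_hist, stack_future, m).da
        deltas.append(pf - ph)
    da = xr.concat(deltas, dim="month").mean("month")
    return ScenarioDelta(da, model_hist.species, scenario, decade)


def percent_change_high(raster_hist: SuitabilityRaster,
                        raster_future: SuitabilityRaster, zone,
                        threshold: float = HIGH_SUITABILITY) -> float | None:
    """% change in highly-suitable cell count within a zone.

    100 x (n_high_future - n_high_hist) / n_high_hist.  Returns None
    (undefined baseline) when the historical raster has no high cells in
    the zone.
    """
    lon2, lat2 = np.meshgrid(raster_hist.lon, raster_hist.lat)
    inside = points_in_zone(zone, lon2.ravel(), lat2.ravel())
    vh = raster_hist.da.values.ravel()[inside]
    vf = raster_future.da.values.ravel()[inside]
    nh = int(np.nansum(vh >= threshold))
    nf = int(np.nansum(vf >= threshold))
    if nh == 0:
        return None
    return float(100.0 * (nf - nh) / nh)


def _check_shared_grid(rasters: list[SuitabilityRaster]) -> None:
    r0 = rasters[0]
    for r in rasters[1:]:
        if (len(r.lon) != len(r0.lon) or len(r.lat) != len(r0.lat)
                or not np.allclose(r.lon, r0.lon)
                or not np.allclose(r.lat, r0.lat)):
            raise ValueError("rasters do not share a grid")
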