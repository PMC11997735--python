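"""End-to-end orchestration: simulate -> tracks -> space use -> SDM -> projection.

`run_pipeline` chains the library stages over a configuration object and
writes the Table-style per-species summary, evaluation reports, zone
summaries, scenario changes, and a machine-readable provenance log.  Every
random choice flows from the single config seed, so a config fully
determines all outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._geo import haversine_km
from .env_covariates import ALL_COVARIATES, annotate, standardize
from .pseudo_absence import N_SIMULATIONS, assemble, background_sample, track_extent
from .projection import (HIGH_SUITABILITY, multispecies_mean, count_high_species,
                         percent_change_high, predict_grid, scenario_delta,
                         summarize_zone)
from .sdm import evaluate, fit_brt, overfit_check
from .space_use import (InsufficientPointsError, area_inside_zone, fit_ud,
                        isopleths, partition_points)
from .synthetic_data import (SyntheticWorld, demo_species, fixture_world,
                             simulate_tracks)
from .track_processing import (DailyTrack, daily_geodesic_median, flag_zones,
                               regularize, remove_colony_points, segment_trips,
                               speed_filter, summarize_depths, tracks_to_csv)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on."""

    out_dir: Path
    seed: int = 0
    months: int = 12
    suitability_threshold: float = HIGH_SUITABILITY
    overfit_tol: float = 0.1
    colony_radius_km: float = 5.0
    trip_dist_km: float = 5.0
    trip_min_duration_h: float = 1.0
    gap_max_days: float = 20.0
    block_size_km2: float = 200.0
    prediction_months: tuple[int, ...] = (5, 11)     # June, December layers
    sdm_hyperparams: dict = field(default_factory=dict)
    scenarios: dict | None = None

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        for name in ("suitability_threshold", "colony_radius_km",
                     "trip_dist_km", "overfit_tol", "gap_max_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def make_demo(out_dir: str | Path, seed: int = 0, months: int = 12) -> SyntheticWorld:
    """Materialize the small three-species fixture world on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world = fixture_world(seed=seed, months=months, species=demo_species())
    world.zones.to_geojson(out / "zones.geojson")
    world.env_hist.to_netcdf(out / "env_hist.nc")
    for name, st in world.env_future.items():
        st.to_netcdf(out / f"env_{name}.nc")
    all_tracks = []
    rng = np.random.default_rng(seed)
    for spec in world.species:
        all_tracks.extend(simulate_tracks(world, spec,
                                          seed=int(rng.integers(2**31 - 1))))
    tracks_to_csv(all_tracks, out / "tracks.csv")
    return world


def process_species_tracks(world: SyntheticWorld, spec, tracks,
                           config: RunConfig) -> tuple[list[DailyTrack], pd.DataFrame]:
    """Clean + regularize + reduce one species' tracks to daily medians."""
    colony = spec.colony or (world.env_hist.ds.attrs.get("atoll_lon"),
                             world.env_hist.ds.attrs.get("atoll_lat"))
    dailies = []
    rows = []
    for tr in tracks:
        t = speed_filter(tr, spec.vmax)
        n_trips = np.nan
        if spec.trip_structure:
            t = remove_colony_points(t, colony, config.colony_radius_km)
            n_trips = len(segment_trips(t, colony, config.trip_dist_km,
                                        config.trip_min_duration_h))
        if len(t) >= 2:
            reg = regularize(t, spec.sample_dt, spec.vmax, config.gap_max_days)
        else:
            reg = t
        daily = daily_geodesic_median(reg)
        # carry the raw depth channel through to the daily summary
        depth = summarize_depths(tr)
        daily = flag_zones(daily, world.zones)
        dailies.append(daily)
        d = daily.data
        dist = (haversine_km(colony[0], colony[1], d["lon"].values,
                             d["lat"].values) if len(d) else np.array([np.nan]))
        row = {"individual_id": tr.individual_id, "species": spec.name,
               "n_raw": len(tr), "n_daily": len(daily),
               "deploy_days": (tr.data["timestamp"].iloc[-1]
                               - tr.data["timestamp"].iloc[0]) / pd.Timedelta(days=1)
               if len(tr) else np.nan,
               "max_dist_km": float(np.nanmax(dist)), "n_trips": n_trips}
        for z in world.zones.names():
            col = f"inside_{z}"
            row[f"frac_{z}"] = float(d[col].mean()) if len(d) else np.nan
        if depth:
            row.update({"mean_daily_max_depth_m": depth["mean_daily_max_m"],
                        "max_depth_m": depth["max_depth_m"]})
        rows.append(row)
    return dailies, pd.DataFrame(rows)


def species_summary(per_individual: pd.DataFrame) -> dict:
    """Table-style species row: mean ± SD over individuals."""
    out = {"n_individuals": int(len(per_individual)),
           "mean_deploy_days": float(per_individual["deploy_days"].mean()),
           "sd_deploy_days": float(per_individual["deploy_days"].std())}
    for c in per_individual.columns:
        if c.startswith("frac_"):
            out[f"pct_{c[5:]}"] = float(100 * per_individual[c].mean())
            out[f"pct_{c[5:]}_sd"] = float(100 * per_individual[c].std())
    out["mean_max_dist_km"] = float(per_individual["max_dist_km"].mean())
    return out


def build_presence_table(dailies: list[DailyTrack], world: SyntheticWorld,
                         seed: int) -> pd.DataFrame:
    """Presences + background pseudo-absences (1:1 per individual),
    annotated with standardized covariates."""
    rng = np.random.default_rng(seed)
    parts = []
    for daily in dailies:
        d = daily.data
        if len(d) == 0:
            continue
        pres = d[["local_day", "lon", "lat"]].copy()
        pres.insert(0, "individual_id", daily.individual_id)
        ext = track_extent(d["lon"].values, d["lat"].values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pool = [background_sample(ext, len(d), rng)
                    for _ in range(N_SIMULATIONS)]
        parts.append(assemble(pres, pool, "background", rng))
    if not parts:
        raise ValueError("no daily locations to model")
    table = pd.concat(parts, ignore_index=True)
    table = annotate(table, world.env_hist)
    n0 = len(table)
    table = table[~table["covariate_missing"]].reset_index(drop=True)
    if len(table) < n0:
        warnings.warn(f"dropped {n0 - len(table)} rows with missing covariates")
    return table


def run_pipeline(config: RunConfig,
                 world: SyntheticWorld | None = None) -> dict:
    """Execute every stage and write the output bundle.

    Returns a dict of the headline results (also written as JSON).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if world is None:
        world = fixture_world(seed=config.seed, months=config.months,
                              species=demo_species(),
                              scenarios=config.scenarios)
    mpa = world.zones["mpa"]
    eez = world.zones["eez"]
    results: dict = {"species": {}}
    summary_rows = {}
    suit_rasters = {m: [] for m in config.prediction_months}
    colony = (world.env_hist.ds.attrs["atoll_lon"],
              world.env_hist.ds.attrs["atoll_lat"])

    for spec in world.species:
        sp_res: dict = {}
        tracks = simulate_tracks(world, spec, seed=int(rng.integers(2**31 - 1)))
        dailies, per_ind = process_species_tracks(world, spec, tracks, config)
        per_ind.to_csv(out / f"individuals_{_slug(spec.name)}.csv", index=False)
        sp_res["summary"] = species_summary(per_ind)
        summary_rows[spec.name] = sp_res["summary"]

        # -- space use: UDs split inside/outside the MPA ------------------
        pts = pd.concat([d.data for d in dailies if len(d)], ignore_index=True)
        inside, outside = partition_points(pts["lon"].values, pts["lat"].values, mpa)
        sp_res["space_use"] = {}
        for part, mask in (("inside", inside), ("outside", outside)):
            if mask.sum() < 5:
                sp_res["space_use"][part] = None   # dashed entry
                continue
            try:
                ud = fit_ud(pts["lon"].values[mask], pts["lat"].values[mask],
                            center=colony)
            except InsufficientPointsError:
                sp_res["space_use"][part] = None
                continue
            iso = isopleths(ud)
            sp_res["space_use"][part] = {
                "area50_km2": iso.area(0.5), "area95_km2": iso.area(0.95),
                "area50_in_mpa_km2": area_inside_zone(iso, 0.5, mpa),
                "n_points": int(mask.sum()), "href_km": ud.bandwidth_h}

        # -- SDM ----------------------------------------------------------
        table = build_presence_table(dailies, world,
                                     seed=int(rng.integers(2**31 - 1)))
        std, scaling = standardize(table, covariates=ALL_COVARIATES)
        covs = [c for c in ALL_COVARIATES if c in std]
        model = fit_brt(std, covs, hyperparams=config.sdm_hyperparams,
                        seed=int(rng.integers(2**31 - 1)),
                        species=spec.name, scaling=scaling)
        report = evaluate(model, std, block_size_km2=config.block_size_km2,
                          seed=int(rng.integers(2**31 - 1)))
        sp_res["sdm"] = {"relative_influence": model.relative_influence.to_dict(),
                         "eval": report.to_dict(),
                         "overfit_pass": overfit_check(report, config.overfit_tol),
                         "n_rows": int(len(std))}

        # -- projection ----------------------------------------------------
        sp_res["projection"] = {}
        hist_rasters = {}
        for m in config.prediction_months:
            ras = predict_grid(model, world.env_hist, m,
                               label=str(world.env_hist.times[m].date()))
            hist_rasters[m] = ras
            suit_rasters[m].append(ras)
            sp_res["projection"][f"month_{m}"] = {
                "mpa": summarize_zone(ras, mpa, config.suitability_threshold),
                "eez": summarize_zone(ras, eez, config.suitability_threshold)}

        sp_res["scenarios"] = {}
        for scen, st_future in world.env_future.items():
            delta = scenario_delta(model, world.env_hist, st_future,
                                   scenario=scen, months=list(config.prediction_months))
            changes = {}
            for m in config.prediction_months:
                fut = predict_grid(model, st_future, m)
                pc = percent_change_high(hist_rasters[m], fut, mpa,
                                         config.suitability_threshold)
                changes[f"month_{m}"] = pc
            lon2 = np.meshgrid(delta.da["lon"].values, delta.da["lat"].values)
            in_mpa = np.asarray(
                world.zones.contains_points("mpa", lon2[0].ravel(), lon2[1].ravel())
            ).reshape(delta.da.shape)
            sp_res["scenarios"][scen] = {
                "mpa_mean_delta": float(np.nanmean(delta.da.values[in_mpa])),
                "pct_change_high_mpa": changes}
        results["species"][spec.name] = sp_res

    # -- cross-species products -------------------------------------------
    results["multispecies"] = {}
    for m in config.prediction_months:
        mean_ras = multispecies_mean(suit_rasters[m])
        counts = count_high_species(suit_rasters[m], config.suitability_threshold)
        mean_ras.to_netcdf(out / f"mean_suitability_month{m}.nc")
        results["multispecies"][f"month_{m}"] = {
            "mpa_mean_suitability": summarize_zone(mean_ras, mpa,
                                                   config.suitability_threshold),
            "max_species_high": int(counts.max())}

    pd.DataFrame(summary_rows).T.to_csv(out / "species_summary.csv")
    results["provenance"] = {"seed": config.seed, "version": __version__,
                             "n_species": len(world.species),
                             "months": config.months}
    (out / "results.json").write_text(json.dumps(results, indent=2, default=_jsonify))
    return results


def _slug(name: str) -> str:
    return name.replace(" ", "_")


def _jsonify(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
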