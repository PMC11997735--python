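"""Synthetic telemetry worlds with known statistical structure.

Generates the three ingredients every downstream stage consumes — monthly
environmental stacks, MPA/EEZ polygons, and multi-species tracks — so the
whole pipeline is testable without data downloads.  The design emulates a
concurrent multi-species tagging campaign at a remote tropical atoll:
nine species across nearshore-pelagic, reef-pelagic, and pelagic guilds,
tag sample rates from 2 min to 12 h, deployment durations from half a day
to nearly a year, central-place foraging trips for breeding seabirds, data
gaps, and occurrence biased by known covariate preferences so habitat
models have a recoverable signal.

Movement is a biased correlated random walk: candidate headings around the
current heading are scored by the local preference-weighted covariate field
plus a persistence term, and sampled through a softmax.  The preference
coefficients act on standardized covariates, giving a known monotone link
between a covariate and usage intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from ._geo import destination_point, haversine_km, wrap_angle
from .env_covariates import DYNAMIC_VARS, EnvStack, SchemaError
from .track_processing import RawTrack
from .zones import ZoneSet, box_zone

GUILDS = ("nearshore-pelagic", "reef-pelagic", "pelagic")

#: Palmyra-like colony / tagging site
DEFAULT_COLONY = (-162.0756, 5.8820)

# realistic tropical-ocean ranges: (mean, amplitude) per covariate
_FIELD_SCALES = {
    "sst": (28.0, 1.5),    # degC
    "chl": (0.12, 0.08),   # mg m-3
    "do": (200.0, 12.0),   # mmol m-3
    "u": (0.0, 0.25),      # m s-1
    "v": (0.0, 0.25),      # m s-1
}


class InvalidGridError(ValueError):
    pass


class InvalidSpecError(ValueError):
    pass


@dataclass
class GridSpec:
    """Regular lon/lat grid: bounds and square cell size in degrees."""

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    cell_deg: float = 0.25

    def __post_init__(self):
        if self.cell_deg <= 0:
            raise InvalidGridError("cell size must be positive")
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise InvalidGridError("grid bounds are empty")

    @property
    def lons(self) -> np.ndarray:
        n = int(round((self.lon_max - self.lon_min) / self.cell_deg))
        return self.lon_min + (np.arange(n) + 0.5) * self.cell_deg

    @property
    def lats(self) -> np.ndarray:
        n = int(round((self.lat_max - self.lat_min) / self.cell_deg))
        return self.lat_min + (np.arange(n) + 0.5) * self.cell_deg

    def contains(self, lon, lat) -> np.ndarray:
        return ((lon >= self.lon_min) & (lon <= self.lon_max)
                & (lat >= self.lat_min) & (lat <= self.lat_max))


@dataclass
class SpeciesSpec:
    """Generator parameters for one species.

    ``preference`` maps covariate names to logistic-scale coefficients on
    standardized covariates; the walk's heading choice is biased by the
    preference-weighted covariate score, so a coefficient of 2 on ``sst``
    makes the species concentrate strongly in warm water.  A covariate
    listed in ``optima`` gets a hump-shaped response instead: the score
    contribution is ``-coef * (z - optimum)**2`` with the optimum in
    standardized units, giving thermal-niche-style selectivity.
    ``max_range_km`` caps excursion distance from the colony (nearshore
    guilds); None leaves the species free to roam the grid.
    """

    name: str
    guild: str
    sample_dt: float                      # seconds between fixes
    n_individuals: int
    deploy_days: tuple[float, float]      # (min, max)
    vmax: float                           # m s-1
    preference: dict[str, float] = field(default_factory=dict)
    trip_structure: bool = False
    colony: tuple[float, float] | None = None
    optima: dict[str, float] = field(default_factory=dict)
    max_range_km: float | None = None
    gap_fraction: float = 0.0
    depth_range_m: tuple[float, float] | None = None

    def __post_init__(self):
        if self.guild not in GUILDS:
            raise InvalidSpecError(f"unknown guild {self.guild!r}")
        if self.sample_dt <= 0:
            raise InvalidSpecError("sample_dt must be positive")
        if self.deploy_days[0] > self.deploy_days[1]:
            raise InvalidSpecError("deploy_days min must be <= max")
        if self.vmax <= 0:
            raise InvalidSpecError("vmax must be positive")


@dataclass
class SyntheticWorld:
    """Everything one analysis run needs: historical and future stacks,
    zone polygons, and the species design."""

    env_hist: EnvStack
    env_future: dict[str, EnvStack]
    zones: ZoneSet
    species: list[SpeciesSpec]
    seed: int
    grid: GridSpec


# ---------------------------------------------------------------------------
# environmental fields

def _smooth_field(shape: tuple[int, int], rng: np.random.Generator,
                  n_waves: int = 4, noise_sigma: float = 4.0) -> np.ndarray:
    """Zero-mean, unit-SD field: low-frequency sinusoids + smoothed noise.

    Cheap, dependency-light, and reproducibly autocorrelated: adjacent
    cells differ far less than random cell pairs.
    """
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    f = np.zeros(shape)
    for _ in range(n_waves):
        kx, ky = rng.uniform(0.5, 2.5, size=2)  # cycles per domain
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        f += amp * np.sin(2 * np.pi * (kx * xx / nx + ky * yy / ny) + phase)
    f += ndimage.gaussian_filter(rng.standard_normal(shape), noise_sigma) * 3.0
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def make_env_stack(grid_spec: GridSpec, months: int = 12, seed: int = 0,
                   atoll_lonlat: tuple[float, float] = DEFAULT_COLONY,
                   start: str = "2022-01-01") -> EnvStack:
    """Monthly covariate stack with a shallow atoll in a deep ocean basin.

    Each dynamic field is a persistent spatial pattern plus a month-specific
    anomaly and (for SST) a seasonal cycle; bathymetry is static, about
    -4500 m far-field with a smooth seamount rising to a -20 m atoll cell.
    """
    if months < 1:
        raise InvalidGridError("months must be >= 1")
    rng = np.random.default_rng(seed)
    lons, lats = grid_spec.lons, grid_spec.lats
    ny, nx = len(lats), len(lons)
    times = pd.date_range(start, periods=months, freq="MS")
    data = {}
    for var in DYNAMIC_VARS:
        mu, amp = _FIELD_SCALES[var]
        base = _smooth_field((ny, nx), rng)
        layers = np.empty((months, ny, nx))
        for m in range(months):
            anom = _smooth_field((ny, nx), rng)
            seasonal = 0.0
            if var == "sst":
                seasonal = 0.6 * np.cos(2 * np.pi * (times[m].month - 3) / 12.0)
            layers[m] = mu + amp * (0.7 * base + 0.3 * anom) + amp * seasonal
        if var == "chl":
            layers = np.maximum(layers, 0.01)
        data[var] = (("time", "lat", "lon"), layers)

    # bathymetry: deep basin + smooth seamount peaking at the atoll cell
    bathy = -4500.0 + 400.0 * _smooth_field((ny, nx), rng)
    dist = haversine_km(atoll_lonlat[0], atoll_lonlat[1],
                        *np.meshgrid(lons, lats))
    bathy = bathy + (4480.0 + 400.0) * np.exp(-(dist / 120.0) ** 2)
    iy = int(np.argmin(np.abs(lats - atoll_lonlat[1])))
    ix = int(np.argmin(np.abs(lons - atoll_lonlat[0])))
    bathy[iy, ix] = -20.0
    bathy = np.minimum(bathy, -15.0)   # keep everything submerged
    data["bathy"] = (("lat", "lon"), bathy)

    ds = xr.Dataset(data, coords={"time": times, "lat": lats, "lon": lons})
    ds.attrs["atoll_lon"] = atoll_lonlat[0]
    ds.attrs["atoll_lat"] = atoll_lonlat[1]
    return EnvStack(ds)


def make_future_stack(env_hist: EnvStack, delta_spec: dict,
                      seed: int | None = None) -> EnvStack:
    """Shifted copy of the historical stack (a climate-scenario stand-in).

    ``delta_spec`` maps covariate name -> shift; a scalar or ``{"add": x}``
    is additive, ``{"mul": y}`` multiplicative.  Bathymetry never changes.
    """
    ds = env_hist.ds.copy(deep=True)
    for var, shift in delta_spec.items():
        if var not in DYNAMIC_VARS:
            raise SchemaError(f"cannot shift unknown covariate {var!r}")
        if isinstance(shift, dict):
            if "add" in shift:
                ds[var] = ds[var] + shift["add"]
            elif "mul" in shift:
                ds[var] = ds[var] * shift["mul"]
            else:
                raise SchemaError(f"shift for {var!r} must use 'add' or 'mul'")
        else:
            ds[var] = ds[var] + float(shift)
    # u/v changed -> derived currents must be refreshed
    ds = ds.drop_vars(["speed", "heading"], errors="ignore")
    return EnvStack(ds)


# ---------------------------------------------------------------------------
# movement

def _preference_score_grids(stack: EnvStack, preference: dict[str, float],
                            optima: dict[str, float] | None = None) -> np.ndarray:
    """Per-month grid of the preference-weighted standardized covariate sum.

    Linear response per covariate, or a hump ``-coef (z - optimum)^2``
    for covariates with a declared optimum.
    """
    optima = optima or {}
    names = set(stack.covariate_names())
    unknown = (set(preference) | set(optima)) - names
    if unknown:
        raise SchemaError(f"preference names not in stack: {sorted(unknown)}")
    nt = len(stack.times)
    ny, nx = len(stack.lat), len(stack.lon)
    score = np.zeros((nt, ny, nx))
    for var, coef in preference.items():
        if coef == 0:
            continue
        da = stack.ds[var]
        if "time" in da.dims:
            arr = da.values
        else:
            arr = np.broadcast_to(da.values, (nt, ny, nx))
        mu, sd = np.nanmean(arr), np.nanstd(arr)
        if sd == 0:
            continue
        z = (arr - mu) / sd
        if var in optima:
            score += -coef * (z - optima[var]) ** 2
        else:
            score += coef * z
    return score


def simulate_tracks(world: SyntheticWorld, spec: SpeciesSpec,
                    seed: int = 0) -> list[RawTrack]:
    """Biased correlated random walks for every individual of a species.

    Step lengths are bounded by ``vmax * sample_dt``; headings persist and
    are attracted toward higher preference-weighted covariate score via a
    softmax over 16 candidate headings.  Central-place species alternate
    foraging trips with returns to the colony; nearshore guilds respect
    ``max_range_km``.  Gaps are injected by dropping contiguous windows.
    """
    stack = world.env_hist
    grid = world.grid
    colony = spec.colony or DEFAULT_COLONY
    if not grid.contains(colony[0], colony[1]):
        raise InvalidSpecError("colony lies outside the grid")
    rng = np.random.default_rng(seed)
    score = _preference_score_grids(stack, spec.preference, spec.optima)
    times_months = stack.times
    t_start_world = times_months[0]
    t_end_world = times_months[-1] + pd.offsets.MonthEnd(0)

    n_cand = 16
    offsets = np.linspace(-np.pi, np.pi, n_cand, endpoint=False)
    kappa = 1.0          # heading-persistence weight
    tracks = []
    for k in range(spec.n_individuals):
        duration_d = rng.uniform(*spec.deploy_days)
        n_steps = max(int(duration_d * 86400 / spec.sample_dt), 2)
        span_d = (t_end_world - t_start_world).days - duration_d - 1
        t0 = t_start_world + pd.Timedelta(days=rng.uniform(0, max(span_d, 0)))
        t0 = t0.tz_localize("UTC") if t0.tzinfo is None else t0
        step_km_max = spec.vmax * spec.sample_dt / 1000.0

        lon, lat = colony
        if not spec.trip_structure:
            # tagged at sea near the atoll
            b = rng.uniform(-np.pi, np.pi)
            lon, lat = destination_point(lon, lat, b, rng.uniform(2, 15))
        heading = rng.uniform(-np.pi, np.pi)
        phase = "out"
        trip_steps_left = _draw_trip_steps(rng, spec, n_steps)

        lons = np.empty(n_steps)
        lats = np.empty(n_steps)
        month_idx = ((t0.tz_localize(None) if t0.tzinfo else t0).to_period("M")
                     - times_months[0].to_period("M")).n
        for i in range(n_steps):
            lons[i], lats[i] = lon, lat
            t_i = t0 + pd.Timedelta(seconds=i * spec.sample_dt)
            mi = min(max(month_idx + (t_i.tz_localize(None).to_period("M")
                                      - t0.tz_localize(None).to_period("M")).n, 0),
                     len(times_months) - 1)
            step = rng.beta(2.0, 2.0) * 0.9 * step_km_max
            cand_head = wrap_angle(heading + offsets)
            clon, clat = destination_point(lon, lat, cand_head, step)
            util = kappa * np.cos(offsets)
            iy, ix, oob = stack.nearest_cell(clon, clat)
            util = util + score[mi, iy, ix]
            bad = oob | ~grid.contains(clon, clat)
            if spec.max_range_km is not None:
                bad |= haversine_km(colony[0], colony[1], clon, clat) > spec.max_range_km
            if spec.trip_structure:
                d_col = haversine_km(colony[0], colony[1], clon, clat)
                if phase == "return":
                    util = util - 0.15 * d_col
            util = np.where(bad, -np.inf, util)
            if not np.isfinite(util).any():
                # boxed in: turn around rather than leave the grid
                heading = wrap_angle(heading + np.pi)
                continue
            u = util - util.max()
            p = np.exp(u)
            p /= p.sum()
            c = rng.choice(n_cand, p=p)
            heading = cand_head[c]
            lon, lat = float(clon[c]), float(clat[c])
            if spec.trip_structure:
                trip_steps_left -= 1
                if phase == "out" and trip_steps_left <= 0:
                    phase = "return"
                elif phase == "return":
                    if haversine_km(colony[0], colony[1], lon, lat) < 3.0:
                        lon, lat = colony
                        heading = rng.uniform(-np.pi, np.pi)
                        phase = "out"
                        trip_steps_left = _draw_trip_steps(rng, spec, n_steps)

        ts = t0 + pd.to_timedelta(np.arange(n_steps) * spec.sample_dt, unit="s")
        df = pd.DataFrame({"timestamp": ts, "lon": lons, "lat": lats})
        if spec.depth_range_m is not None:
            lo, hi = spec.depth_range_m
            df["depth_m"] = rng.uniform(lo, hi, size=n_steps)
        if spec.gap_fraction > 0 and n_steps > 20:
            df = _inject_gaps(df, spec.gap_fraction, rng)
        tracks.append(RawTrack(df.reset_index(drop=True),
                               individual_id=f"{spec.name}-{k + 1:02d}",
                               species=spec.name, tag_type="synthetic"))
    return tracks


def _draw_trip_steps(rng: np.random.Generator, spec: SpeciesSpec,
                     n_steps: int) -> int:
    # trips last ~6-36 h of outbound movement, capped by the deployment
    out_s = rng.uniform(6, 36) * 3600
    return max(int(out_s / spec.sample_dt), 2)


def _inject_gaps(df: pd.DataFrame, frac: float,
                 rng: np.random.Generator) -> pd.DataFrame:
    n = len(df)
    n_drop = int(frac * n)
    keep = np.ones(n, dtype=bool)
    while n_drop > 0:
        w = min(max(int(rng.exponential(n * frac / 3)) + 1, 1), n_drop)
        s = rng.integers(1, n - 1)
        keep[s:s + w] = False
        n_drop -= w
    keep[0] = keep[-1] = True
    return df[keep]


# ---------------------------------------------------------------------------
# study designs

def species_table() -> list[SpeciesSpec]:
    """The full nine-species design: three seabirds, two cetaceans, two
    pelagic fishes, reef manta ray, grey reef shark.  Sample rates span
    2 min to 12 h and deployments 0.5-350 days, as in a mixed GPS /
    satellite / pop-up-archival campaign."""
    c = DEFAULT_COLONY
    return [
        SpeciesSpec("red-footed booby", "nearshore-pelagic", 120, 8, (0.5, 60),
                    41.7, {"sst": 0.6, "chl": 0.8, "bathy": 0.5}, True, c,
                    max_range_km=170, gap_fraction=0.02),
        SpeciesSpec("great frigatebird", "pelagic", 300, 7, (30, 300), 25.0,
                    {"sst": 1.0, "chl": 0.5}, True, c, gap_fraction=0.02),
        SpeciesSpec("sooty tern", "pelagic", 21600, 12, (3, 20), 13.9,
                    {"chl": 1.2, "do": 0.5}, True, c),
        SpeciesSpec("bottlenose dolphin", "nearshore-pelagic", 3600, 5, (14, 25),
                    5.6, {"bathy": 1.5}, False, c, max_range_km=50,
                    depth_range_m=(5, 700)),
        SpeciesSpec("melon-headed whale", "nearshore-pelagic", 3600, 8, (8, 18),
                    5.6, {"bathy": 1.0, "chl": 0.5}, False, c, max_range_km=120,
                    depth_range_m=(10, 650)),
        SpeciesSpec("yellowfin tuna", "pelagic", 43200, 9, (30, 180), 10.0,
                    {"sst": 2.0, "do": -0.8}, False, c,
                    depth_range_m=(5, 1100)),
        SpeciesSpec("blue marlin", "pelagic", 43200, 1, (60, 70), 10.0,
                    {"sst": 1.0}, False, c, depth_range_m=(5, 350)),
        SpeciesSpec("reef manta ray", "reef-pelagic", 43200, 4, (80, 350), 3.0,
                    {"chl": 1.5, "do": -0.5}, False, c, depth_range_m=(5, 770)),
        SpeciesSpec("grey reef shark", "reef-pelagic", 43200, 6, (150, 350),
                    2.5, {"bathy": 1.0, "chl": 0.8}, False, c,
                    depth_range_m=(5, 440), gap_fraction=0.02),
    ]


def demo_species() -> list[SpeciesSpec]:
    """Three-species fixture (one per guild) sized to run in minutes."""
    c = DEFAULT_COLONY
    return [
        SpeciesSpec("bottlenose dolphin", "nearshore-pelagic", 3600, 5, (14, 22),
                    5.6, {"bathy": 1.5}, False, c, max_range_km=50,
                    depth_range_m=(5, 700)),
        SpeciesSpec("grey reef shark", "reef-pelagic", 43200, 6, (120, 300),
                    2.5, {"bathy": 1.0, "chl": 0.8}, False, c,
                    depth_range_m=(5, 440)),
        SpeciesSpec("yellowfin tuna", "pelagic", 43200, 9, (40, 150), 10.0,
                    {"sst": 2.0, "do": -0.8}, False, c,
                    depth_range_m=(5, 1100)),
    ]


def fixture_world(seed: int = 0, months: int = 12,
                  species: list[SpeciesSpec] | None = None,
                  scenarios: dict[str, dict] | None = None) -> SyntheticWorld:
    """The standard test world: 20 deg x 20 deg grid at 0.25 deg, 12 monthly
    layers, a ~1.9 deg-half-width MPA box around the colony inside a larger
    EEZ box (mimicking 50 nm / 200 nm zoning), plus two warmed future
    scenarios."""
    c = DEFAULT_COLONY
    grid = GridSpec(c[0] - 10, c[0] + 10, c[1] - 10, c[1] + 10, 0.25)
    env = make_env_stack(grid, months=months, seed=seed, atoll_lonlat=c)
    if scenarios is None:
        scenarios = {"ssp126": {"sst": 1.0, "do": -4.0},
                     "ssp370": {"sst": 2.5, "chl": {"mul": 0.9}, "do": -10.0}}
    env_future = {name: make_future_stack(env, d) for name, d in scenarios.items()}
    zones = ZoneSet({"mpa": box_zone(c[0], c[1], 1.9),
                     "eez": box_zone(c[0], c[1], 6.0),
                     "extent": box_zone(c[0], c[1], 10.0)})
    return SyntheticWorld(env, env_future, zones,
                          species or demo_species(), seed, grid)
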