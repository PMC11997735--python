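import numpy as np
import pandas as pd
import pytest

from mpatrack import synthetic_data as sd
from mpatrack._geo import haversine_km
from mpatrack.env_covariates import DYNAMIC_VARS, SchemaError, annotate


@pytest.fixture(scope="module")
def grid():
    c = sd.DEFAULT_COLONY
    return sd.GridSpec(c[0] - 10, c[0] + 10, c[1] - 10, c[1] + 10, 0.25)


class TestMakeEnvStack:
    def test_same_seed_bit_identical(self, grid):
        a = sd.make_env_stack(grid, months=2, seed=5)
        b = sd.make_env_stack(grid, months=2, seed=5)
        for v in DYNAMIC_VARS + ("bathy",):
            np.testing.assert_array_equal(a.ds[v].values, b.ds[v].values)

    def test_atoll_shallower_than_far_field(self, grid):
        st = sd.make_env_stack(grid, months=1, seed=5)
        bathy = st.ds["bathy"].values
        iy, ix, _ = st.nearest_cell(*sd.DEFAULT_COLONY)
        corner = bathy[0, 0]   # far from the atoll
        assert bathy[iy[0], ix[0]] > corner
        assert bathy[iy[0], ix[0]] == pytest.approx(-20.0)

    def test_spatial_autocorrelation_each_field(self, grid, rng):
        st = sd.make_env_stack(grid, months=1, seed=5)
        for v in DYNAMIC_VARS:
            f = st.layer(v, 0)
            adjacent = np.abs(np.diff(f, axis=1)).mean()
            i = rng.integers(0, f.shape[0], 4000)
            j = rng.integers(0, f.shape[1], 4000)
            i2 = rng.integers(0, f.shape[0], 4000)
            j2 = rng.integers(0, f.shape[1], 4000)
            random_pairs = np.abs(f[i, j] - f[i2, j2]).mean()
            assert adjacent < random_pairs, v

    def test_invalid_cell_size(self):
        with pytest.raises(sd.InvalidGridError):
            sd.GridSpec(0, 1, 0, 1, cell_deg=0)


class TestMakeFutureStack:
    def test_zero_shift_identity(self, world):
        fut = sd.make_future_stack(world.env_hist, {})
        for v in DYNAMIC_VARS:
            np.testing.assert_array_equal(fut.ds[v].values,
                                          world.env_hist.ds[v].values)

    def test_sst_shift_exact(self, world):
        fut = sd.make_future_stack(world.env_hist, {"sst": 2.0})
        np.testing.assert_allclose(fut.ds["sst"].values,
                                   world.env_hist.ds["sst"].values + 2.0)

    def test_multiplicative_shift(self, world):
        fut = sd.make_future_stack(world.env_hist, {"chl": {"mul": 0.5}})
        np.testing.assert_allclose(fut.ds["chl"].values,
                                   world.env_hist.ds["chl"].values * 0.5)

    def test_bathymetry_unchanged(self, world):
        fut = sd.make_future_stack(world.env_hist, {"sst": 3.0})
        np.testing.assert_array_equal(fut.ds["bathy"].values,
                                      world.env_hist.ds["bathy"].values)

    def test_unknown_covariate_rejected(self, world):
        with pytest.raises(SchemaError):
            sd.make_future_stack(world.env_hist, {"salinity": 1.0})
        with pytest.raises(SchemaError):
            sd.make_future_stack(world.env_hist, {"bathy": 1.0})


class TestSimulateTracks:
    def test_determinism(self, world):
        spec = world.species[0]
        a = sd.simulate_tracks(world, spec, seed=3)
        b = sd.simulate_tracks(world, spec, seed=3)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.data, tb.data)

    def test_vmax_honored_and_bounds_and_time_order(self, world):
        for spec in world.species:
            for t in sd.simulate_tracks(world, spec, seed=4):
                d = t.data
                ts = d["timestamp"].astype("int64").values / 1e9
                assert (np.diff(ts) > 0).all()
                assert world.grid.contains(d["lon"].values, d["lat"].values).all()
                v = haversine_km(d["lon"][:-1].values, d["lat"][:-1].values,
                                 d["lon"][1:].values, d["lat"][1:].values) \
                    * 1000.0 / np.diff(ts)
                assert (v <= spec.vmax + 1e-9).all()

    def test_colony_outside_grid_rejected(self, world):
        spec = sd.SpeciesSpec("stray", "pelagic", 3600, 1, (1, 2), 5.0,
                              {}, False, colony=(0.0, 0.0))
        with pytest.raises(sd.InvalidSpecError):
            sd.simulate_tracks(world, spec, seed=0)

    def test_zero_preference_used_matches_available(self, world):
        """An indifferent walker samples covariates like the background:
        |standardized used-available difference| < 0.1 at n >= 5000."""
        spec = sd.SpeciesSpec("driftfish", "pelagic", 7200, 8, (60, 90),
                              8.0, {}, False)
        tracks = sd.simulate_tracks(world, spec, seed=9)
        pts = pd.concat([t.data for t in tracks], ignore_index=True)
        assert len(pts) >= 5000
        pts["local_day"] = pts["timestamp"].dt.date
        ann = annotate(pts, world.env_hist)
        for v in ("sst", "chl", "do"):
            arr = world.env_hist.ds[v].values
            z = (ann[v].mean() - np.nanmean(arr)) / np.nanstd(arr)
            assert abs(z) < 0.1, (v, z)

    def test_sst_preference_shifts_usage(self, world, rng):
        spec = sd.SpeciesSpec("warmfish", "pelagic", 21600, 4, (30, 60),
                              8.0, {"sst": 2.0}, False)
        tracks = sd.simulate_tracks(world, spec, seed=9)
        pts = pd.concat([t.data for t in tracks], ignore_index=True)
        pts["local_day"] = pts["timestamp"].dt.date
        used = annotate(pts, world.env_hist)["sst"].mean()
        bg_lon = rng.uniform(world.grid.lon_min, world.grid.lon_max, 4000)
        bg_lat = rng.uniform(world.grid.lat_min, world.grid.lat_max, 4000)
        bg = pd.DataFrame({"lon": bg_lon, "lat": bg_lat,
                           "local_day": pts["local_day"].iloc[0]})
        available = annotate(bg, world.env_hist)["sst"].mean()
        assert used > available

    def test_nearshore_guild_stays_inside_mpa(self, world):
        spec = next(s for s in world.species if s.guild == "nearshore-pelagic")
        for t in sd.simulate_tracks(world, spec, seed=6):
            inside = world.zones.contains_points("mpa", t.data["lon"].values,
                                                 t.data["lat"].values)
            assert inside.all()


def test_species_table_spans_study_design():
    specs = sd.species_table()
    assert len(specs) == 9
    assert {s.guild for s in specs} == set(sd.GUILDS)
    rates = [s.sample_dt for s in specs]
    assert min(rates) == 120 and max(rates) == 43200
    lo = min(s.deploy_days[0] for s in specs)
    hi = max(s.deploy_days[1] for s in specs)
    assert lo == 0.5 and hi == 350
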