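import numpy as np
import pandas as pd
import pytest
import xarray as xr

from mpatrack import env_covariates as ec
from mpatrack import synthetic_data as sd
from mpatrack._geo import haversine_km


class TestDeriveCurrents:
    @pytest.mark.parametrize("u,v,speed,heading", [
        (3.0, 4.0, 5.0, np.arctan2(4, 3)),
        (0.0, 0.0, 0.0, 0.0),
        (1.0, 1.0, np.sqrt(2), np.pi / 4),
    ])
    def test_exact_values(self, u, v, speed, heading):
        s, h = ec.derive_currents(np.array([u]), np.array([v]))
        assert s[0] == pytest.approx(speed, abs=1e-12)
        assert h[0] == pytest.approx(heading, abs=1e-12)

    def test_nan_propagates_and_ranges(self, rng):
        u = rng.normal(size=100)
        v = rng.normal(size=100)
        u[3] = np.nan
        s, h = ec.derive_currents(u, v)
        assert np.isnan(s[3])
        ok = ~np.isnan(s)
        assert (s[ok] >= 0).all()
        assert ((h[ok] > -np.pi) & (h[ok] <= np.pi)).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            ec.derive_currents(np.zeros(3), np.zeros(4))


class TestAnnotate:
    def test_cell_center_exact(self, world):
        st = world.env_hist
        iy, ix = 10, 20
        pts = pd.DataFrame({"lon": [st.lon[ix]], "lat": [st.lat[iy]],
                            "local_day": [st.times[1].date()]})
        out = ec.annotate(pts, st)
        assert out["sst"].iloc[0] == st.layer("sst", 1)[iy, ix]
        assert out["bathy"].iloc[0] == st.ds["bathy"].values[iy, ix]
        assert not out["covariate_missing"].iloc[0]

    def test_outside_grid_flagged_not_dropped(self, world):
        pts = pd.DataFrame({"lon": [0.0], "lat": [0.0],
                            "local_day": [world.env_hist.times[0].date()]})
        out = ec.annotate(pts, world.env_hist)
        assert len(out) == 1
        assert out["covariate_missing"].iloc[0]
        assert np.isnan(out["sst"].iloc[0])

    def test_matches_brute_force_nearest_cell(self, world, rng):
        st = world.env_hist
        n = 60
        pts = pd.DataFrame({
            "lon": rng.uniform(st.lon[0], st.lon[-1], n),
            "lat": rng.uniform(st.lat[0], st.lat[-1], n),
            "local_day": [st.times[2].date()] * n})
        out = ec.annotate(pts, st)
        lon2, lat2 = np.meshgrid(st.lon, st.lat)
        sst = st.layer("sst", 2)
        for k in range(n):
            d = haversine_km(pts["lon"][k], pts["lat"][k], lon2, lat2)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            assert out["sst"].iloc[k] == sst[i, j]


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        t = pd.DataFrame({"sst": rng.normal(28, 2, 400),
                          "chl": rng.gamma(2, 0.05, 400)})
        std, params = ec.standardize(t, covariates=("sst", "chl"))
        for c in ("sst", "chl"):
            assert std[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert std[c].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_stored_params_reproduce(self, rng):
        t = pd.DataFrame({"sst": rng.normal(28, 2, 100)})
        std, params = ec.standardize(t, covariates=("sst",))
        again, _ = ec.standardize(t, params=params)
        np.testing.assert_allclose(again["sst"], std["sst"])

    def test_constant_column_dropped(self):
        t = pd.DataFrame({"sst": [1.0, 1.0, 1.0], "chl": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            std, params = ec.standardize(t, covariates=("sst", "chl"))
        assert "sst" not in std
        assert "sst" not in params.mean


class TestMonthlyMedianComposite:
    def _stack(self, years, fill, seed=0):
        grid = sd.GridSpec(-164, -160, 4, 8, 1.0)
        months = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-01", freq="MS")
        st = sd.make_env_stack(grid, months=len(months), seed=seed,
                               start=f"{years[0]}-01-01")
        if fill is not None:
            for v in ec.DYNAMIC_VARS:
                st.ds[v] = xr.full_like(st.ds[v], fill)
        return st

    def test_single_year_identity_per_month(self):
        st = self._stack([2000], None)
        comp = ec.monthly_median_composite([st], (2000, 2000))
        for m in range(12):
            np.testing.assert_allclose(comp.layer("sst", m), st.layer("sst", m))

    def test_median_of_three_years(self):
        stacks = [self._stack([2000, 2002], None, seed=1)]
        st = stacks[0]
        # force cell values {1, 2, 9} for january across the three years
        sst = st.ds["sst"].values.copy()
        jan = [i for i, t in enumerate(st.times) if t.month == 1]
        for i, val in zip(jan, [1.0, 9.0, 2.0]):
            sst[i] = val
        st.ds["sst"] = (("time", "lat", "lon"), sst)
        comp = ec.monthly_median_composite(stacks, (2000, 2002))
        assert np.unique(comp.layer("sst", 0)) == np.array([2.0])

    def test_two_stage_median_across_datasets(self):
        a = self._stack([2000], 1.0)
        b = self._stack([2000], 2.0)
        c = self._stack([2000], 9.0)
        comp = ec.monthly_median_composite([a, b, c], (2000, 2000))
        assert np.unique(comp.layer("chl", 5)) == np.array([2.0])

    def test_matches_brute_force_oracle(self):
        stacks = [self._stack([2000, 2001], None, seed=s) for s in (3, 4)]
        comp = ec.monthly_median_composite(stacks, (2000, 2001))
        # brute force: per stack, per calendar month, median over years; then
        # median across stacks
        for month in (1, 7):
            per = []
            for st in stacks:
                idx = [i for i, t in enumerate(st.times) if t.month == month]
                per.append(np.median([st.layer("do", i) for i in idx], axis=0))
            oracle = np.median(per, axis=0)
            np.testing.assert_allclose(comp.layer("do", month - 1), oracle)

    def test_composite_idempotent(self):
        st = self._stack([2000], None, seed=6)
        c1 = ec.monthly_median_composite([st], (2000, 2000))
        c2 = ec.monthly_median_composite([c1], (2000, 2000))
        np.testing.assert_allclose(c1.ds["sst"].values, c2.ds["sst"].values)

    def test_uncovered_range_errors(self):
        st = self._stack([2000], None)
        with pytest.raises(ValueError):
            ec.monthly_median_composite([st], (1990, 1995))
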