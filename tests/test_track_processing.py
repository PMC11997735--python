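import numpy as np
import pandas as pd
import pytest

from conftest import make_track
from mpatrack import track_processing as tp
from mpatrack._geo import destination_point, haversine_km
from mpatrack.zones import box_zone

PALMYRA = (-162.0756, 5.8820)


class TestTrim:
    def test_window_covering_all_is_identity(self):
        t = make_track([-162 + i * 0.01 for i in range(10)], [5.9] * 10)
        out = tp.trim_to_deployment(t, "2022-05-01", "2022-07-01")
        pd.testing.assert_frame_equal(out.data, t.data)

    def test_window_excluding_all_warns_empty(self):
        t = make_track([-162.0] * 5, [5.9] * 5)
        with pytest.warns(UserWarning):
            out = tp.trim_to_deployment(t, "2023-01-01", "2023-02-01")
        assert len(out) == 0

    def test_partial_window_keeps_exact_count(self):
        t = make_track([-162.0] * 10, [5.9] * 10, t0="2022-06-01 00:00", dt_s=3600)
        out = tp.trim_to_deployment(t, "2022-06-01 02:00", "2022-06-01 06:00")
        assert len(out) == 5  # fixes 3..7


class TestSpeedFilter:
    def test_fast_pair_drops_second(self):
        lon2, lat2 = destination_point(-162.0, 5.9, 0.5, 100.0)
        t = make_track([-162.0, lon2], [5.9, lat2], dt_s=3600)  # 27.8 m/s
        assert len(tp.speed_filter(t, 25.0)) == 1
        assert len(tp.speed_filter(t, 40.0)) == 2

    def test_teleporting_outliers_removed_exactly(self, rng):
        # a slow 1 m/s walk with 5 injected distant outliers
        n = 60
        lons, lats = [-162.0], [5.9]
        for _ in range(n - 1):
            lo, la = destination_point(lons[-1], lats[-1],
                                       rng.uniform(-np.pi, np.pi), 3.0)
            lons.append(float(lo)), lats.append(float(la))
        outlier_idx = [7, 19, 30, 42, 55]
        for i in outlier_idx:
            lo, la = destination_point(lons[i], lats[i], 1.0, 500.0)
            lons[i], lats[i] = float(lo), float(la)
        t = make_track(lons, lats, dt_s=3600)   # base speed ~0.83 m/s
        out = tp.speed_filter(t, vmax=5.0)
        kept_times = set(out.data["timestamp"])
        all_times = list(t.data["timestamp"])
        removed = [i for i, ts in enumerate(all_times) if ts not in kept_times]
        assert removed == outlier_idx

    def test_output_satisfies_own_precondition(self, rng):
        lons = -162 + np.cumsum(rng.uniform(-0.5, 0.5, 40))
        lats = 5.9 + np.cumsum(rng.uniform(-0.5, 0.5, 40))
        out = tp.speed_filter(make_track(lons, lats, dt_s=3600), vmax=10.0)
        d = out.data
        ts = d["timestamp"].astype("int64").values / 1e9
        v = haversine_km(d["lon"][:-1].values, d["lat"][:-1].values,
                         d["lon"][1:].values, d["lat"][1:].values) * 1000 / np.diff(ts)
        assert (v <= 10.0 + 1e-9).all()


class TestColonyRemoval:
    def test_point_at_center_removed_and_boundary_convention(self):
        lon51, lat51 = destination_point(*PALMYRA, 0.0, 5.1)
        t = make_track([PALMYRA[0], lon51], [PALMYRA[1], lat51])
        out = tp.remove_colony_points(t, PALMYRA, 5.0)
        assert len(out) == 1
        assert out.data["lat"].iloc[0] == pytest.approx(lat51)

    def test_matches_brute_force_haversine(self, rng):
        lons = PALMYRA[0] + rng.uniform(-0.3, 0.3, 200)
        lats = PALMYRA[1] + rng.uniform(-0.3, 0.3, 200)
        t = make_track(lons, lats, dt_s=600)
        out = tp.remove_colony_points(t, PALMYRA, 5.0)
        expected = sum(haversine_km(PALMYRA[0], PALMYRA[1], lo, la) >= 5.0
                       for lo, la in zip(lons, lats))
        assert len(out) == expected


class TestTrips:
    def make_excursion(self, dists_km, dt_s=1800):
        lons, lats = [], []
        for d in dists_km:
            lo, la = destination_point(*PALMYRA, 0.8, d)
            lons.append(float(lo)), lats.append(float(la))
        return make_track(lons, lats, dt_s=dt_s)

    def test_never_beyond_threshold_no_trips(self):
        t = self.make_excursion([1, 2, 3, 2, 1])
        assert tp.segment_trips(t, PALMYRA) == []

    def test_single_long_excursion(self):
        t = self.make_excursion([1, 10, 20, 15, 1])  # 3 away-fixes over 1 h
        trips = tp.segment_trips(t, PALMYRA, min_duration_h=1.0)
        assert len(trips) == 1
        assert trips[0].max_distance_km == pytest.approx(20, rel=0.01)

    def test_short_excursion_filtered_by_duration(self):
        # 30-min excursion then a 3-h one
        dists = [1, 10, 1, 1, 8, 12, 15, 12, 8, 1]
        t = self.make_excursion(dists, dt_s=1800)
        trips = tp.segment_trips(t, PALMYRA, min_duration_h=1.0)
        assert len(trips) == 1
        assert trips[0].duration_h >= 1.0


class TestRegularize:
    def test_already_regular_identity(self):
        t = make_track([-162 + i * 0.01 for i in range(6)],
                       [5.9 + i * 0.01 for i in range(6)], dt_s=3600)
        out = tp.regularize(t, 3600)
        np.testing.assert_allclose(out.data["lon"], t.data["lon"], atol=1e-9)
        np.testing.assert_allclose(out.data["lat"], t.data["lat"], atol=1e-9)

    def test_midpoint_is_great_circle_midpoint(self):
        t = make_track([-165.0, -158.0], [4.0, 8.0], dt_s=7200)
        out = tp.regularize(t, 3600)
        mid = out.data.iloc[1]
        d1 = haversine_km(-165, 4, mid["lon"], mid["lat"])
        d2 = haversine_km(mid["lon"], mid["lat"], -158, 8)
        assert d1 == pytest.approx(d2, rel=1e-6)

    def test_interpolated_points_within_bracketing_bbox(self, rng):
        lons = -162 + np.cumsum(rng.uniform(-0.2, 0.2, 20))
        lats = 5.9 + np.cumsum(rng.uniform(-0.2, 0.2, 20))
        raw = make_track(lons, lats, dt_s=5400)
        out = tp.regularize(raw, 1800)
        ts_raw = raw.data["timestamp"].astype("int64").values / 1e9
        for _, row in out.data.iterrows():
            t = row["timestamp"].timestamp()
            j = np.searchsorted(ts_raw, t, side="right") - 1
            j = min(max(j, 0), len(ts_raw) - 2)
            lo = sorted([lons[j], lons[j + 1]])
            la = sorted([lats[j], lats[j + 1]])
            assert lo[0] - 1e-6 <= row["lon"] <= lo[1] + 1e-6
            assert la[0] - 1e-6 <= row["lat"] <= la[1] + 1e-6

    def test_long_gap_not_interpolated(self):
        df = pd.DataFrame({
            "timestamp": pd.to_datetime(["2022-06-01", "2022-06-02",
                                         "2022-07-15", "2022-07-16"], utc=True),
            "lon": [-162.0, -161.5, -158.0, -157.5],
            "lat": [5.9, 6.0, 8.0, 8.1]})
        t = tp.RawTrack(df, "g1", "testfish")
        out = tp.regularize(t, 43200, gap_max_days=20)
        assert set(out.data["segment"]) == {0, 1}
        # no emitted fix inside the gap
        gap_lo = pd.Timestamp("2022-06-03", tz="UTC")
        gap_hi = pd.Timestamp("2022-07-14", tz="UTC")
        mids = out.data["timestamp"].between(gap_lo, gap_hi)
        assert not mids.any()


class TestDailyMedian:
    def test_single_fix_day_is_identity(self):
        t = make_track([-162.0], [5.9])
        out = tp.daily_geodesic_median(t)
        assert len(out) == 1
        assert out.data["lon"].iloc[0] == -162.0

    def test_identical_fixes(self):
        t = make_track([-162.0] * 8, [5.9] * 8, dt_s=600)
        out = tp.daily_geodesic_median(t)
        assert out.data["lon"].iloc[0] == pytest.approx(-162.0, abs=1e-8)

    def test_one_row_per_local_day(self, rng):
        n = 96
        t = make_track(list(-162 + rng.uniform(0, 1, n)),
                       list(5.9 + rng.uniform(0, 1, n)), dt_s=3600)
        out = tp.daily_geodesic_median(t)
        assert out.data["local_day"].is_unique
        assert out.data["n_fixes"].sum() == n

    def test_hst_day_boundary(self):
        # 09:59 and 10:01 UTC straddle the HST midnight
        df = pd.DataFrame({
            "timestamp": pd.to_datetime(["2022-06-01 09:59", "2022-06-01 10:01"],
                                        utc=True),
            "lon": [-162.0, -161.0], "lat": [5.9, 6.0]})
        out = tp.daily_geodesic_median(tp.RawTrack(df, "h1", "testfish"))
        assert len(out) == 2


class TestDepths:
    def test_constant_depth(self):
        t = make_track([-162.0] * 5, [5.9] * 5, depth=[100.0] * 5)
        s = tp.summarize_depths(t)
        assert s["mean_daily_max_m"] == 100.0
        assert s["sd_daily_max_m"] == 0.0
        assert s["max_depth_m"] == 100.0

    def test_two_day_maxima(self):
        # 10:00 UTC is HST midnight, so fixes pair up 2-per-local-day
        t = make_track([-162.0] * 4, [5.9] * 4, t0="2022-06-01 10:00",
                       dt_s=12 * 3600, depth=[50, 100, 300, 200])
        s = tp.summarize_depths(t)
        assert s["mean_daily_max_m"] == pytest.approx(200.0)  # {100, 300}
        assert s["max_depth_m"] == 300.0

    def test_no_depth_channel(self):
        assert tp.summarize_depths(make_track([-162.0], [5.9])) is None

    def test_matches_groupby_oracle(self, rng):
        n = 120
        t = make_track([-162.0] * n, [5.9] * n, dt_s=3600,
                       depth=list(rng.uniform(0, 500, n)))
        s = tp.summarize_depths(t)
        days = tp.local_day(t.data["timestamp"])
        oracle = t.data.groupby(days)["depth_m"].max()
        assert s["mean_daily_max_m"] == pytest.approx(oracle.mean())
        assert s["sd_daily_max_m"] == pytest.approx(oracle.std(ddof=1))


def _ray_cast(poly_coords, x, y):
    """Even-odd rule point-in-polygon oracle."""
    inside = False
    n = len(poly_coords)
    for i in range(n - 1):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[i + 1]
        if (y1 > y) != (y2 > y):
            xi = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xi:
                inside = not inside
    return inside


class TestPercentInside:
    def test_all_at_centroid(self):
        zone = box_zone(-162.0, 5.9, 1.0)
        t = make_track([-162.0] * 5, [5.9] * 5, dt_s=86400)
        daily = tp.daily_geodesic_median(t)
        assert tp.percent_inside(daily, zone) == 1.0

    def test_six_of_ten(self):
        zone = box_zone(-162.0, 5.9, 0.5)
        lons = [-162.0] * 6 + [-160.0] * 4
        t = make_track(lons, [5.9] * 10, dt_s=86400)
        daily = tp.daily_geodesic_median(t)
        assert tp.percent_inside(daily, zone) == 0.6

    def test_empty_daily_track_errors(self):
        daily = tp.DailyTrack(pd.DataFrame(columns=["local_day", "lon", "lat"]),
                              "e1", "testfish")
        with pytest.raises(ValueError):
            tp.percent_inside(daily, box_zone(0, 0, 1))

    def test_matches_ray_casting_oracle(self, rng):
        zone = box_zone(-162.0, 5.9, 1.3)
        coords = list(zone.exterior.coords)
        lons = -162.0 + rng.uniform(-2, 2, 100)
        lats = 5.9 + rng.uniform(-2, 2, 100)
        t = make_track(list(lons), list(lats), dt_s=86400)
        daily = tp.daily_geodesic_median(t)
        d = daily.data
        oracle = np.mean([_ray_cast(coords, lo, la)
                          for lo, la in zip(d["lon"], d["lat"])])
        assert tp.percent_inside(daily, zone) == pytest.approx(oracle)
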