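"""Trait extraction: screening, windowing, rates, activity index, roads."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from shapely.geometry import LineString

from harvestsel.errors import ConfigurationError, DataError
from harvestsel.traits import (
    RoadNetwork,
    activity_index,
    daily_activity,
    distance_to_road,
    home_range_and_density,
    movement_rates,
    screen_fixes,
    window_study_period,
    _julian_date,
)

TZ = "Europe/Stockholm"


def _fixes(times, xs, ys, dop=None, bear="B1"):
    return pd.DataFrame(dict(
        bear_id=bear,
        timestamp=pd.to_datetime(times).tz_localize(TZ),
        x=xs, y=ys,
        dop=dop if dop is not None else np.ones(len(xs)),
    ))


class TestScreening:
    def test_strictly_greater_than_threshold_is_removed(self):
        fixes = _fixes(["2015-08-02 00:00", "2015-08-02 01:00", "2015-08-02 02:00"],
                       [0, 0, 0], [0, 0, 0], dop=[5.0, 10.0, 10.1])
        res = screen_fixes(fixes)
        assert res.fixes["dop"].tolist() == [5.0, 10.0]
        assert res.n_removed == 1

    def test_empty_input_is_vacuous(self):
        res = screen_fixes(_fixes([], [], [], dop=[]))
        assert len(res.fixes) == 0 and res.fraction_removed == 0.0

    def test_removed_count_matches_direct_tally(self):
        rng = np.random.default_rng(3)
        dop = rng.uniform(0, 9, 1000)
        dop[rng.choice(1000, 30, replace=False)] = rng.uniform(10.5, 20, 30)
        times = pd.date_range("2015-08-01", periods=1000, freq="h").astype(str)
        res = screen_fixes(_fixes(times, np.zeros(1000), np.zeros(1000), dop=dop))
        assert len(res.fixes) == 970
        assert res.fraction_removed == pytest.approx(0.03)

    def test_missing_dop_is_a_data_error(self):
        bad = _fixes(["2015-08-02 00:00"], [0], [0]).drop(columns="dop")
        with pytest.raises(DataError):
            screen_fixes(bad)


class TestWindow:
    def test_boundaries_are_inclusive_aug1_to_sep30(self):
        fixes = _fixes(
            ["2015-07-31 23:59", "2015-08-01 00:00", "2015-09-30 23:59",
             "2015-10-01 00:00"],
            [0, 0, 0, 0], [0, 0, 0, 0],
        )
        kept = window_study_period(fixes)
        got = kept["timestamp"].dt.strftime("%m-%d").tolist()
        assert got == ["08-01", "09-30"]

    def test_year_filter(self):
        fixes = _fixes(["2014-08-15 12:00", "2015-08-15 12:00"], [0, 0], [0, 0])
        assert len(window_study_period(fixes, year=2015)) == 1


class TestMovementRates:
    def test_three_four_five_triangle(self):
        fixes = _fixes(["2015-08-02 04:00", "2015-08-02 05:00"], [0, 300], [0, 400])
        rates = movement_rates(fixes)
        assert rates["rate"].tolist() == [500.0]
        assert rates["hour"].tolist() == [4]

    def test_stationary_bear_has_zero_rate(self):
        fixes = _fixes(["2015-08-02 04:00", "2015-08-02 05:00"], [5, 5], [7, 7])
        assert movement_rates(fixes)["rate"].tolist() == [0.0]

    def test_two_hour_gap_emits_nothing(self):
        fixes = _fixes(["2015-08-02 04:00", "2015-08-02 06:00"], [0, 100], [0, 0])
        assert len(movement_rates(fixes)) == 0

    def test_matches_brute_force_pairing_on_random_track(self):
        rng = np.random.default_rng(11)
        t0 = pd.Timestamp("2015-08-02 00:00", tz=TZ)
        times, gaps = [t0], rng.choice([60, 60, 60, 55, 65, 120, 30], 99)
        for g in gaps:
            times.append(times[-1] + pd.Timedelta(minutes=int(g)))
        xs, ys = rng.normal(0, 500, 100), rng.normal(0, 500, 100)
        fixes = pd.DataFrame(dict(bear_id="B1", timestamp=times, x=xs, y=ys, dop=1.0))
        got = movement_rates(fixes)["rate"].to_numpy()
        expected = []
        for i in range(99):
            gap = (times[i + 1] - times[i]).total_seconds() / 60.0
            if 55.0 <= gap <= 65.0:
                expected.append(float(np.hypot(xs[i + 1] - xs[i], ys[i + 1] - ys[i])))
        assert np.allclose(np.sort(got), np.sort(expected))


def _interval(day="2015-08-21", start_h=5, end_h=15):
    start = pd.Timestamp(f"{day} {start_h:02d}:00", tz=TZ)
    end = pd.Timestamp(f"{day} {end_h:02d}:00", tz=TZ)
    d_h = (end - start).total_seconds() / 3600.0
    return start, end, d_h, 24.0 - d_h


def _samples(hours, values, day="2015-08-21"):
    return pd.DataFrame(dict(
        bear_id="B1",
        timestamp=[pd.Timestamp(f"{day} 00:00", tz=TZ) + pd.Timedelta(hours=h)
                   for h in hours],
        value=values,
    ))


class TestActivityIndex:
    def test_hand_evaluated_case_is_exact(self):
        """SA_h=300 over 10 h against SA_nh=140 over 14 h gives (30-10)/(30+10)."""
        s = _samples([6.0, 10.0, 2.0, 20.0], [100.0, 200.0, 70.0, 70.0])
        res = activity_index(s, _interval())
        assert res["index"] == pytest.approx(0.5, abs=1e-12)

    def test_only_active_during_hunting_hours_gives_one(self):
        s = _samples([6.0, 2.0], [50.0, 0.0])
        assert activity_index(s, _interval())["index"] == 1.0

    def test_only_active_outside_hunting_hours_gives_minus_one(self):
        s = _samples([6.0, 2.0], [0.0, 50.0])
        assert activity_index(s, _interval())["index"] == -1.0

    def test_equal_rates_give_zero(self):
        s = _samples([6.0, 2.0], [10.0, 14.0])  # 10/10 vs 14/14
        assert activity_index(s, _interval())["index"] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_activity_day_is_dropped(self):
        s = _samples([6.0, 2.0], [0.0, 0.0])
        assert activity_index(s, _interval()) is None

    def test_no_coverage_of_one_period_is_dropped(self):
        assert activity_index(_samples([6.0, 7.0], [5.0, 5.0]), _interval()) is None

    def test_window_straddling_boundary_goes_with_its_midpoint(self):
        # window starting 2.4 minutes before the hunting start has its
        # midpoint inside -> counts wholly as hunting-hour activity
        s = _samples([6.0, 5.0 - 2.4 / 60.0, 2.0], [0.0, 30.0, 10.0])
        res = activity_index(s, _interval())
        assert res["sa_h"] == 30.0 and res["sa_nh"] == 10.0

    @given(st.lists(st.tuples(st.floats(0, 23.9), st.floats(0, 1e4)),
                    min_size=2, max_size=50))
    def test_index_is_bounded(self, pairs):
        hours = [p[0] for p in pairs]
        values = [p[1] for p in pairs]
        res = activity_index(_samples(hours, values), _interval())
        if res is not None:
            assert -1.0 <= res["index"] <= 1.0

    def test_vectorized_daily_table_matches_per_day_reference(self):
        rng = np.random.default_rng(4)
        frames = []
        for day in ("2015-08-20", "2015-08-21", "2015-08-22"):
            hours = rng.uniform(0, 24, 40)
            frames.append(_samples(hours, rng.uniform(0, 10, 40), day=day))
        act = pd.concat(frames, ignore_index=True)
        table, dropped = daily_activity(act)
        assert dropped == 0 and len(table) == 3
        from harvestsel.traits import _hunting_interval
        for _, row in table.iterrows():
            day = pd.Timestamp(row["date"])
            sub = act[act["timestamp"].dt.date == day.date()]
            ref = activity_index(sub, _hunting_interval(day.date(), 61.0, 15.0, TZ))
            assert row["index"] == pytest.approx(ref["index"], abs=1e-12)


class TestRoads:
    def test_on_road_vertex_is_zero(self):
        roads = RoadNetwork([LineString([(0, 0), (1000, 0)])])
        fixes = _fixes(["2015-08-02 04:00"], [0], [0])
        per_fix, _ = distance_to_road(fixes, roads)
        assert per_fix["dist_road"].iloc[0] == 0.0

    def test_perpendicular_distance_to_axis(self):
        roads = RoadNetwork([LineString([(-1000, 0), (1000, 0)])])
        fixes = _fixes(["2015-08-02 04:00"], [0], [100])
        per_fix, _ = distance_to_road(fixes, roads)
        assert per_fix["dist_road"].iloc[0] == pytest.approx(100.0)

    def test_daily_mean_is_arithmetic_mean(self):
        roads = RoadNetwork([LineString([(-1e4, 0), (1e4, 0)])])
        fixes = _fixes(
            ["2015-08-02 04:00", "2015-08-02 05:00", "2015-08-02 06:00"],
            [0, 0, 0], [0, 100, 200],
        )
        _, daily = distance_to_road(fixes, roads)
        assert daily["mean_dist"].tolist() == [100.0]

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        xs, ys = rng.uniform(0, 1000, 20), rng.uniform(0, 1000, 20)
        times = pd.date_range("2015-08-02", periods=20, freq="h").astype(str)
        line = [(100, -50), (700, 900)]
        d0, _ = distance_to_road(_fixes(times, xs, ys), RoadNetwork([LineString(line)]))
        shift = np.array([123.4, -987.6])
        moved = [(p[0] + shift[0], p[1] + shift[1]) for p in line]
        d1, _ = distance_to_road(_fixes(times, xs + shift[0], ys + shift[1]),
                                 RoadNetwork([LineString(moved)]))
        assert np.allclose(d0["dist_road"], d1["dist_road"])

    def test_empty_network_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            distance_to_road(_fixes(["2015-08-02 04:00"], [0], [0]), RoadNetwork([]))


def _brute_force_hull_area(points):
    """O(n^3) convex hull: a directed pair is a hull edge iff every other
    point lies on its left; shoelace over the angularly ordered vertices."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    on_hull = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.all(cross >= -1e-9):
                on_hull.add(i)
                on_hull.add(j)
    verts = pts[sorted(on_hull)]
    c = verts.mean(axis=0)
    order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
    v = verts[order]
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


class TestHomeRange:
    def test_unit_square_with_one_crossing_road(self):
        xs = [0, 1000, 1000, 0]
        ys = [0, 0, 1000, 1000]
        times = pd.date_range("2015-08-02", periods=4, freq="h").astype(str)
        roads = RoadNetwork([LineString([(500, 0), (500, 1000)])])
        _, density = home_range_and_density(_fixes(times, xs, ys), roads)
        assert density == pytest.approx(1.0)  # 1 km of road in 1 km^2

    def test_no_intersecting_roads_gives_zero_density(self):
        xs = [0, 1000, 1000, 0]
        ys = [0, 0, 1000, 1000]
        times = pd.date_range("2015-08-02", periods=4, freq="h").astype(str)
        roads = RoadNetwork([LineString([(5000, 0), (5000, 1000)])])
        _, density = home_range_and_density(_fixes(times, xs, ys), roads)
        assert density == 0.0

    def test_collinear_fixes_are_a_data_error(self):
        times = pd.date_range("2015-08-02", periods=3, freq="h").astype(str)
        with pytest.raises(DataError):
            home_range_and_density(_fixes(times, [0, 10, 20], [0, 10, 20]),
                                   RoadNetwork([LineString([(0, 0), (1, 1)])]))

    def test_mcp_area_matches_exhaustive_hull_oracle(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            pts = rng.uniform(0, 2000, size=(rng.integers(5, 20), 2))
            times = pd.date_range("2015-08-02", periods=len(pts), freq="h").astype(str)
            hull, _ = home_range_and_density(
                _fixes(times, pts[:, 0], pts[:, 1]),
                RoadNetwork([LineString([(0, 0), (1, 1)])]),
            )
            assert hull.area == pytest.approx(_brute_force_hull_area(pts), rel=1e-9)


def test_julian_date_zero_is_21_august():
    jd = _julian_date(pd.to_datetime(["2015-08-21", "2015-08-01", "2015-09-30"]),
                      [2015, 2015, 2015])
    assert jd.tolist() == [0.0, -20.0, 40.0]
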