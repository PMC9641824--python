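"""Daylight subsampling, daily metrics, day classification, endpoints and
distance summaries on constructed tracks."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from stopover.geodesy import rhumb_destination, rhumb_distance
from stopover.movement import (
    MigrationSummary,
    SegmentationConfig,
    TrackOutcome,
    classify_day,
    daily_metrics,
    detect_endpoint,
    migration_summary,
    segment_track,
    subsample_daylight,
)
from stopover.solar import sunrise_sunset

CFG = SegmentationConfig()


def fixes_frame(times, lats, lons, acc=1.0, ind="b1"):
    n = len(times)
    return pd.DataFrame(
        {
            "individual_id": [ind] * n,
            "timestamp": pd.to_datetime(times, utc=True),
            "lat": lats,
            "lon": lons,
            "acc_var": np.broadcast_to(acc, (n,)).astype(float),
        }
    )


def day_times(date, lat, lon, minutes):
    rise, set_ = sunrise_sunset(date, lat, lon)
    out = []
    t = rise
    while t <= set_:
        out.append(t)
        t += dt.timedelta(minutes=minutes)
    return out


class TestSubsample:
    def test_ten_minute_fixes_reduce_to_hourly_slots(self):
        date = dt.date(2019, 4, 10)
        times = day_times(date, 30.0, 35.0, 10)
        fx = fixes_frame(times, [30.0] * len(times), [35.0] * len(times))
        sub = subsample_daylight(fx, CFG)
        rise, set_ = sunrise_sunset(date, 30.0, 35.0)
        n_slots = int((set_ - rise).total_seconds() // 3600) + 1
        assert abs(len(sub) - n_slots) <= 1

    def test_hourly_daylight_fixes_unchanged(self):
        date = dt.date(2019, 4, 10)
        times = day_times(date, 30.0, 35.0, 60)
        fx = fixes_frame(times, np.linspace(30, 30.5, len(times)), [35.0] * len(times))
        sub = subsample_daylight(fx, CFG)
        pd.testing.assert_frame_equal(sub.reset_index(drop=True), fx)

    def test_night_only_fixes_dropped(self):
        times = [dt.datetime(2019, 4, 10, 22, 0, tzinfo=dt.timezone.utc),
                 dt.datetime(2019, 4, 10, 23, 30, tzinfo=dt.timezone.utc)]
        fx = fixes_frame(times, [30.0, 30.0], [35.0, 35.0])
        assert subsample_daylight(fx, CFG).empty

    def test_empty_input(self):
        fx = fixes_frame([], [], [])
        assert subsample_daylight(fx, CFG).empty


class TestDailyMetrics:
    def _day(self, lats, lons):
        times = [dt.datetime(2019, 4, 10, 6 + i, 0, tzinfo=dt.timezone.utc)
                 for i in range(len(lats))]
        return fixes_frame(times, lats, lons)

    def test_stationary_day(self):
        seg = daily_metrics(self._day([30, 30, 30], [35, 35, 35]))
        assert seg["total_distance_km"] == 0
        assert seg["beeline_km"] == 0
        assert np.isnan(seg["azimuth_deg"])

    def test_out_and_back(self):
        seg = daily_metrics(self._day([30, 31, 30], [35, 35, 35]))
        d = rhumb_distance(30, 35, 31, 35)
        assert seg["beeline_km"] == pytest.approx(0, abs=1e-9)
        assert seg["total_distance_km"] == pytest.approx(2 * d)

    def test_turning_angle_wraps(self):
        prev = pd.Series({"azimuth_deg": 10.0})
        seg = daily_metrics(self._day([30, 30], [35, 34]), prev)  # due west = 270
        assert seg["turning_angle_deg"] == pytest.approx(100, abs=1e-6)

    def test_first_day_has_no_turning_angle(self):
        seg = daily_metrics(self._day([30, 31], [35, 35]))
        assert np.isnan(seg["turning_angle_deg"])

    def test_single_fix_degenerate(self):
        seg = daily_metrics(self._day([30], [35]))
        assert seg["degenerate"]
        assert seg["total_distance_km"] == 0

    def test_beeline_never_exceeds_total(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            lats = 30 + np.cumsum(rng.normal(0, 0.1, size=8))
            lons = 35 + np.cumsum(rng.normal(0, 0.1, size=8))
            seg = daily_metrics(self._day(lats, lons))
            assert seg["beeline_km"] <= seg["total_distance_km"] + 1e-6


class TestClassifyDay:
    @pytest.mark.parametrize(
        "total, beeline, expected",
        [(45, 10, "migratory"), (25, 20, "migratory"), (30, 15, "stopover"),
         (40, 19, "stopover"), (40.01, 0, "migratory"), (0, 19.01, "migratory")],
    )
    def test_threshold_rule(self, total, beeline, expected):
        seg = pd.Series({"total_distance_km": total, "beeline_km": beeline})
        assert classify_day(seg, CFG) == expected


def build_track(day_specs, start=(29.55, 34.95), start_date=dt.date(2019, 4, 10),
                interval=60):
    """Hand-built fix stream: one (step_km, heading, acc) spec per day."""
    lat, lon = start
    rows = []
    for i, (step, heading, acc) in enumerate(day_specs):
        date = start_date + dt.timedelta(days=i)
        times = day_times(date, lat, lon, interval)
        frac = np.linspace(0, 1, len(times))
        la, lo = rhumb_destination(lat, lon, heading, step * frac)
        rows.append(fixes_frame(times, np.atleast_1d(la), np.atleast_1d(lo), acc))
        lat, lon = float(np.atleast_1d(la)[-1]), float(np.atleast_1d(lo)[-1])
    return pd.concat(rows, ignore_index=True)


class TestEndpoints:
    def test_arrival_after_reverse_turn(self):
        specs = [(200, 10, 1.0)] * 5 + [(10, 190, 0.4)] + [(3, 120, 0.4)] * 3
        fx = build_track(specs)
        segs = segment_track(fx, CFG)
        out = detect_endpoint(segs, fx, CFG)
        assert out.endpoint == "arrival"
        assert out.endpoint_date == segs["date"].iloc[5]
        # arrival location is the previous day's roost
        assert out.endpoint_lat == pytest.approx(segs["roost_end_lat"].iloc[4])

    def test_death_on_flat_acc_and_no_movement(self):
        specs = [(200, 10, 1.0)] * 3 + [(0.01, 0, 0.001)] * 3
        fx = build_track(specs)
        segs = segment_track(fx, CFG)
        out = detect_endpoint(segs, fx, CFG)
        assert out.endpoint == "death"
        assert out.endpoint_date == segs["date"].iloc[3]

    def test_loss_when_stream_just_ends(self):
        specs = [(200, 10, 1.0)] * 4
        fx = build_track(specs)
        segs = segment_track(fx, CFG)
        out = detect_endpoint(segs, fx, CFG)
        assert out.endpoint == "loss"

    def test_stopover_turn_is_not_arrival_when_migration_resumes(self):
        # a sharp-turn stopover day followed by northern long-distance days
        specs = [(200, 10, 1.0)] * 3 + [(5, 200, 0.4)] + [(200, 10, 1.0)] * 3
        fx = build_track(specs)
        segs = segment_track(fx, CFG)
        out = detect_endpoint(segs, fx, CFG)
        assert out.endpoint == "loss"  # neither arrival nor death fires

    def test_empty_segments_is_loss(self):
        fx = build_track([(200, 10, 1.0)])
        out = detect_endpoint(segment_track(fx.iloc[0:0], CFG), fx, CFG)
        assert out.endpoint == "loss"


class TestMigrationSummary:
    def _segments(self, classes, dists):
        return pd.DataFrame(
            {
                "date": [dt.date(2019, 4, 10) + dt.timedelta(days=i) for i in range(len(classes))],
                "day_class": classes,
                "total_distance_km": dists,
            }
        )

    def test_all_stopover_gives_zero(self):
        segs = self._segments(["stopover"] * 4, [5, 5, 5, 5])
        out = TrackOutcome("loss", segs["date"].iloc[-1])
        s = migration_summary(segs, out, (29.55, 34.95))
        assert s.post_eilat_distance_km == 0
        assert s.n_stopover_days == 4 and s.n_migratory_days == 0

    def test_total_distance_is_two_rhumb_legs(self):
        segs = self._segments(["migratory"], [100.0])
        out = TrackOutcome("arrival", dt.date(2019, 4, 12), 55.0, 60.0)
        winter, capture, breeding = (-25.0, 30.0), (29.55, 34.95), (55.0, 60.0)
        s = migration_summary(segs, out, capture, winter, breeding)
        expected = rhumb_distance(*winter, *capture) + rhumb_distance(*capture, *breeding)
        assert s.total_migration_distance_km == pytest.approx(expected)

    def test_death_at_capture_roost(self):
        segs = self._segments(["stopover", "stopover"], [1.0, 0.5])
        out = TrackOutcome("death", segs["date"].iloc[1], 29.5502, 34.9502)
        s = migration_summary(segs, out, (29.55, 34.95))
        assert s.distance_until_death_km < 0.1
        assert s.days_until_death == 1

    def test_breeding_point_for_non_arrival_warns(self):
        segs = self._segments(["migratory"], [100.0])
        out = TrackOutcome("loss", segs["date"].iloc[-1])
        with pytest.warns(UserWarning):
            s = migration_summary(segs, out, (29.55, 34.95), (-25.0, 30.0), (55.0, 60.0))
        assert np.isnan(s.total_migration_distance_km)

    def test_day_counts_partition_pre_endpoint_days(self):
        segs = self._segments(["migratory", "stopover", "migratory"], [50, 5, 60])
        out = TrackOutcome("arrival", segs["date"].iloc[2], 30.0, 35.0)
        s = migration_summary(segs, out, (29.55, 34.95))
        assert s.n_migratory_days + s.n_stopover_days == 2  # days before arrival


def test_summary_dataclass_defaults():
    s = MigrationSummary(0.0, 0, 0)
    assert np.isnan(s.total_migration_distance_km)
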