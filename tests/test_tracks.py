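import datetime as dt

import numpy as np
import pytest
from shapely.geometry import Polygon

from aggresidence import tracks
from aggresidence.types import ArgosPosition, PositionSource, ValidationError


def ts(*args):
    return dt.datetime(*args)


def pos(shark, when, lat, lon, cls="C2", source=PositionSource.ARGOS):
    return ArgosPosition(shark, when, lat, lon, cls, source)


class TestHaversine:
    def test_identical_points(self):
        assert tracks.haversine_km((20.0, 40.0), (20.0, 40.0)) == 0.0

    def test_one_degree_of_latitude(self):
        assert tracks.haversine_km((0.0, 0.0), (1.0, 0.0)) == pytest.approx(111.19, abs=0.01)

    def test_antipodal_half_circumference(self):
        assert tracks.haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(20015.09, abs=0.01)

    def test_symmetry(self):
        a, b = (19.5, 39.8), (21.2, 41.1)
        assert tracks.haversine_km(a, b) == tracks.haversine_km(b, a)


class TestFilterArgos:
    def test_all_class_z_dropped(self):
        series = [pos("WS1", ts(2012, 3, 1, h), 20.0, 40.0, "Z") for h in range(5)]
        assert tracks.filter_argos(series) == []

    def test_middle_speed_violation_dropped(self):
        # middle point ~108 km in 1 h (30 m/s) both ways; outer pair compliant
        series = [
            pos("WS1", ts(2012, 3, 1, 0), 20.0, 40.0, "B"),
            pos("WS1", ts(2012, 3, 1, 1), 20.975, 40.0, "B"),
            pos("WS1", ts(2012, 3, 1, 2), 20.05, 40.0, "B"),
        ]
        out = tracks.filter_argos(series)
        assert [p.timestamp.hour for p in out] == [0, 2]

    def test_compliant_track_unchanged_and_idempotent(self):
        series = [
            pos("WS1", ts(2012, 3, 1, h), 20.0 + 0.01 * h, 40.0, "A") for h in range(6)
        ]
        once = tracks.filter_argos(series)
        assert once == series
        assert tracks.filter_argos(once) == once

    def test_on_land_positions_dropped(self):
        land = Polygon([(41, 19), (42, 19), (42, 21), (41, 21)])
        series = [
            pos("WS1", ts(2012, 3, 1, 0), 20.0, 40.0, "B"),
            pos("WS1", ts(2012, 3, 2, 0), 20.0, 41.5, "B"),  # inside land
        ]
        out = tracks.filter_argos(series, land=land)
        assert len(out) == 1 and out[0].lon == 40.0

    def test_output_speeds_all_compliant(self):
        rng = np.random.default_rng(3)
        t0 = ts(2012, 3, 1)
        series = [
            pos("WS1", t0 + dt.timedelta(hours=6 * i),
                20.0 + float(rng.normal(0, 0.5)), 40.0 + float(rng.normal(0, 0.5)), "B")
            for i in range(50)
        ]
        out = tracks.filter_argos(series)
        for a, b in zip(out, out[1:]):
            dist_m = tracks.haversine_km((a.lat, a.lon), (b.lat, b.lon)) * 1000
            dt_s = (b.timestamp - a.timestamp).total_seconds()
            assert dist_m / dt_s <= 4.0 + 1e-9


class TestMergeKnownPositions:
    def test_acoustic_days_become_c2_pseudo_positions(self):
        days = {
            dt.date(2012, 3, 1 + i): [(20.0, 40.0)] for i in range(3)
        }
        out = tracks.merge_known_positions("WS1", [], days, {})
        assert len(out) == 3
        assert all(p.error_class == "C2" and p.source == PositionSource.ACOUSTIC_PSEUDO
                   for p in out)

    def test_two_station_day_uses_centroid(self):
        days = {dt.date(2012, 3, 1): [(20.0, 40.0), (20.2, 40.4)]}
        (p,) = tracks.merge_known_positions("WS1", [], days, {})
        assert p.lat == pytest.approx(20.1) and p.lon == pytest.approx(40.2)

    def test_argos_and_encounter_same_day_both_retained(self):
        argos = [pos("WS1", ts(2012, 3, 1, 4), 20.5, 40.5, "B")]
        enc = {dt.date(2012, 3, 1): (20.0, 40.0)}
        out = tracks.merge_known_positions("WS1", argos, {}, enc)
        assert len(out) == 2
        assert out[0].timestamp < out[1].timestamp

    def test_merge_never_loses_argos_positions(self):
        argos = [pos("WS1", ts(2012, 3, 1, h), 20.0, 40.0, "B") for h in (1, 5, 9)]
        out = tracks.merge_known_positions(
            "WS1", argos, {dt.date(2012, 3, 2): [(20.0, 40.0)]}, {}
        )
        assert len(out) >= len(argos)

    def test_positions_time_ordered(self):
        argos = [pos("WS1", ts(2012, 3, 5, 4), 20.5, 40.5, "B")]
        days = {dt.date(2012, 3, 1): [(20.0, 40.0)], dt.date(2012, 3, 9): [(20.0, 40.0)]}
        out = tracks.merge_known_positions("WS1", argos, days, {})
        stamps = [p.timestamp for p in out]
        assert stamps == sorted(stamps)


HOME = (20.0, 40.0)
BASIN = Polygon([(32, 12.5), (44, 12.5), (44, 30), (32, 30)])  # (lon, lat)


def km_south(km):
    return HOME[0] - km / 111.19


class TestClassifyBehavior:
    def _track(self, points):
        return tracks.FusedTrack("WS1", [
            pos("WS1", when, lat, lon, cls) for when, lat, lon, cls in points
        ])

    def test_local_only(self):
        track = self._track([
            (ts(2012, 3, 1), 20.0, 40.0, "C2"),
            (ts(2012, 6, 1), km_south(40), 40.0, "B"),
        ])
        label = tracks.classify_behavior(track, HOME, {2012: True}, basin=BASIN)
        assert label == "local_only"
        assert track.max_displacement_km < 100

    def test_interannual_return(self):
        track = self._track([
            (ts(2012, 4, 1), 20.0, 40.0, "C2"),
            (ts(2012, 9, 1), km_south(500), 40.0, "B"),
            (ts(2013, 4, 1), 20.0, 40.0, "C2"),
        ])
        label = tracks.classify_behavior(track, HOME, {2012: True, 2013: True}, basin=BASIN)
        assert label == "interannual_return"

    def test_multi_year_return(self):
        points = [(ts(2012, 4, 1), 20.0, 40.0, "C2"),
                  (ts(2012, 9, 1), km_south(500), 40.0, "B")]
        for year in (2013, 2014):
            points.append((ts(year, 4, 1), 20.0, 40.0, "C2"))
        track = self._track(points)
        label = tracks.classify_behavior(
            track, HOME, {2012: True, 2013: True, 2014: True}, basin=BASIN
        )
        assert label == "multi_year_return"

    def test_same_year_excursion(self):
        track = self._track([
            (ts(2012, 4, 1), 20.0, 40.0, "C2"),
            (ts(2012, 5, 15), km_south(300), 40.0, "B"),
            (ts(2012, 6, 20), 20.0, 40.0, "C2"),
        ])
        label = tracks.classify_behavior(track, HOME, {2012: True}, basin=BASIN)
        assert label == "excursion_return_same_year"

    def test_emigrant_stays_in_basin(self):
        track = self._track([
            (ts(2012, 4, 1), 20.0, 40.0, "C2"),
            (ts(2012, 10, 1), 13.0, 41.0, "B"),  # far, but inside basin
        ])
        label = tracks.classify_behavior(track, HOME, {2012: False}, basin=BASIN)
        assert label == "emigrant"

    def test_emigrant_left_basin(self):
        track = self._track([
            (ts(2012, 4, 1), 20.0, 40.0, "C2"),
            (ts(2012, 11, 1), 11.0, 43.0, "B"),  # south of the basin edge
        ])
        label = tracks.classify_behavior(track, HOME, {}, basin=BASIN)
        assert label == "emigrant_left_basin"

    def test_empty_track_rejected(self):
        with pytest.raises(ValidationError):
            tracks.classify_behavior(tracks.FusedTrack("WS1", []), HOME, {})


class TestMonthlyLatitudeSummary:
    def test_single_month_contribution(self):
        track = tracks.FusedTrack("WS1", [
            pos("WS1", ts(2012, 4, 1 + i), 20.0 - 0.1 * i, 40.0) for i in range(5)
        ])
        summary = tracks.monthly_latitude_summary([track])
        assert summary[4][1] == 1 and len(summary[4][0]) == 5
        for month in set(range(1, 13)) - {4}:
            assert summary[month] == ([], 0)

    def test_shark_counts_bounded_by_cohort(self):
        cohort = [
            tracks.FusedTrack(f"WS{i}", [pos(f"WS{i}", ts(2012, m, 2), 19.0, 40.0)
                                         for m in range(1, 13)])
            for i in range(4)
        ]
        summary = tracks.monthly_latitude_summary(cohort)
        assert all(n <= 4 for _lats, n in summary.values())
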