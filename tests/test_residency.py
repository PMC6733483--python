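import datetime as dt
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from aggresidence import effort as effort_mod, residency as rm
from aggresidence.types import Detection, StudyWindow, ValidationError


def ts(*args):
    return dt.datetime(*args)


def day(*args):
    return dt.date(*args)


@pytest.fixture
def window():
    return StudyWindow(dt.date(2012, 1, 1), dt.date(2012, 12, 31), timezone_offset_hours=3)


class TestDetectionDays:
    def test_many_detections_collapse_to_one_day(self, window):
        dets = [
            Detection("T1", "S1" if i % 2 else "S2", ts(2012, 4, 2, 6, i))
            for i in range(40)
        ]
        out = rm.detection_days(dets, {"T1": "WS1"}, window)
        array_days, by_station = out["WS1"]
        assert array_days == {day(2012, 4, 2)}
        assert by_station["S1"] == by_station["S2"] == {day(2012, 4, 2)}

    def test_zero_detections_empty(self, window):
        assert rm.detection_days([], {"T1": "WS1"}, window) == {}

    def test_local_midnight_boundary_splits_days(self, window):
        # 21:30 UTC = 00:30 local (+3): next local day
        dets = [
            Detection("T1", "S1", ts(2012, 4, 2, 20, 0)),
            Detection("T1", "S1", ts(2012, 4, 2, 21, 30)),
        ]
        (array_days, _) = rm.detection_days(dets, {"T1": "WS1"}, window)["WS1"]
        assert array_days == {day(2012, 4, 2), day(2012, 4, 3)}


class TestResidenceIndices:
    def test_r_min_full_residency(self):
        assert rm.r_min(10, day(2012, 1, 1), day(2012, 1, 10)) == 1.0

    def test_r_min_ratio(self):
        # 5 detected days, monitored 100 days inclusive
        assert rm.r_min(5, day(2012, 1, 1), day(2012, 4, 9)) == 0.05

    def test_r_min_zero_days(self):
        assert rm.r_min(0, day(2012, 1, 1), day(2012, 4, 9)) == 0.0

    def test_r_max_single_detection_on_tagging_day(self):
        assert rm.r_max(1, day(2012, 3, 1), day(2012, 3, 1)) == 1.0

    def test_r_max_ratio_and_bound(self):
        # 4 days detected, last detection 16 days after tagging (inclusive span)
        value = rm.r_max(4, day(2012, 1, 1), day(2012, 1, 16))
        assert value == 0.25
        r_min_value = rm.r_min(4, day(2012, 1, 1), day(2012, 6, 8))  # 160-day study
        assert r_min_value == 4 / 160 <= value

    def test_r_max_undefined_without_detections(self):
        assert rm.r_max(0, day(2012, 1, 1), None) is None


class TestRSpatial:
    array_days = {day(2012, 4, d) for d in (1, 2, 3, 4)}
    station_days = {day(2012, 4, 1), day(2012, 4, 2)}

    def test_full_effort(self):
        active = {day(2012, 4, d) for d in range(1, 30)}
        assert rm.r_spatial(self.station_days, self.array_days, active) == 0.5

    def test_inactive_day_excluded_from_denominator(self):
        active = {day(2012, 4, d) for d in (1, 2, 3)}  # down on the 4th
        value = rm.r_spatial(self.station_days, self.array_days, active)
        assert value == pytest.approx(2 / 3)
        assert round(value, 2) == 0.67

    def test_never_visited_station_zero(self):
        active = {day(2012, 4, d) for d in range(1, 30)}
        assert rm.r_spatial(set(), self.array_days, active) == 0.0

    def test_undefined_when_station_never_active_on_array_days(self):
        assert rm.r_spatial(set(), self.array_days, set()) is None


class TestDpueAndFractions:
    def test_dpue_direct_ratio(self, window, basic_station):
        st = basic_station(intervals=[(ts(2012, 1, 1), ts(2012, 2, 20))])  # 50 days
        table = effort_mod.build_effort_table([st], StudyWindow(day(2012, 1, 1), day(2012, 2, 19)))
        dets = [Detection("T1", st.station_id, ts(2012, 1, 5, 1, 0, i % 60, i)) for i in range(100)]
        assert rm.dpue(dets, table, {st.station_id}) == 2.0

    def test_dpue_zero_detections(self, window, basic_station):
        st = basic_station()
        table = effort_mod.build_effort_table([st], StudyWindow(day(2012, 1, 1), day(2012, 1, 10)))
        assert rm.dpue([], table, {st.station_id}) == 0.0

    def test_dpue_zero_effort_undefined(self, basic_station):
        st = basic_station(intervals=[])
        table = effort_mod.build_effort_table([st], StudyWindow(day(2012, 1, 1), day(2012, 1, 10)))
        assert rm.dpue([], table, {st.station_id}) is None

    def test_monthly_fractions_sum_to_one(self, window):
        dets = (
            [Detection("T1", "S1", ts(2012, 4, 1 + i)) for i in range(24)]
            + [Detection("T1", "S1", ts(2012, 5, 1 + i % 13)) for i in range(13)]
            + [Detection("T1", "S1", ts(2012, 6, 1 + i % 13)) for i in range(13)]
        )
        fractions = rm.monthly_fractions(dets, window)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert fractions[4] == pytest.approx(0.48)
        assert fractions[5] == fractions[6] == pytest.approx(0.26)

    def test_all_in_one_month(self, window):
        dets = [Detection("T1", "S1", ts(2012, 4, 1 + i)) for i in range(5)]
        assert rm.monthly_fractions(dets, window)[4] == 1.0


def mann_whitney_oracle(a, b):
    """Exact two-sided p by full enumeration of group assignments."""
    pooled = np.array(list(a) + list(b), dtype=float)
    n_a = len(a)
    ranks = rankdata(pooled)

    def u_of(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2

    u_obs = u_of(range(n_a))
    mean = len(a) * len(b) / 2
    dev_obs = abs(u_obs - mean)
    all_u = [u_of(c) for c in combinations(range(len(pooled)), n_a)]
    p = sum(1 for u in all_u if abs(u - mean) >= dev_obs - 1e-12) / len(all_u)
    return u_obs, min(1.0, p)


class TestCompareGroups:
    def test_identical_constant_groups(self):
        u, p = rm.compare_groups([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert u == 4.5  # n_a*n_b/2 with midranks
        assert p == 1.0

    def test_separated_groups_exact(self):
        u, p = rm.compare_groups([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            rm.compare_groups([], [1.0])

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 4, 7], [2, 3, 9]),
            ([1, 1, 2], [2, 3, 3]),          # ties across groups
            ([0.5, 2.5], [1.5, 3.5, 4.5]),
            ([10, 20, 30, 40, 50], [15, 25, 35, 45, 55]),
            ([1, 2, 2, 2], [2, 2, 3]),        # heavy ties
        ],
    )
    def test_exact_path_matches_enumeration_oracle(self, a, b):
        u, p = rm.compare_groups(a, b)
        u_expected, p_expected = mann_whitney_oracle(a, b)
        # U may be reported from either orientation
        assert u in (u_expected, len(a) * len(b) - u_expected)
        assert p == pytest.approx(p_expected, abs=1e-9)

    def test_type_i_error_calibration(self):
        """Null rejection rate at alpha=.05 stays inside the binomial CI."""
        rng = np.random.default_rng(42)
        n_reps, alpha = 1000, 0.05
        rejections = sum(
            rm.compare_groups(rng.normal(size=12), rng.normal(size=12))[1] < alpha
            for _ in range(n_reps)
        )
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rejections / n_reps - alpha) < 1.96 * se + 1e-12


class TestBonferroni:
    def test_sixty_three_station_array(self):
        assert round(rm.bonferroni_alpha(0.05, 63), 4) == 0.0008

    def test_identity(self):
        assert rm.bonferroni_alpha(0.05, 1) == 0.05

    def test_direct_division(self):
        assert rm.bonferroni_alpha(0.01, 10) == pytest.approx(0.001)

    def test_zero_comparisons_error(self):
        with pytest.raises(ValidationError):
            rm.bonferroni_alpha(0.05, 0)


class TestComputeResidencyProperties:
    def test_bracket_and_bounds_on_simulation(self, small_scenario):
        sc = small_scenario
        window = sc.config.window
        table = effort_mod.build_effort_table(sc.stations, window)
        records = rm.compute_residency(sc.detections, sc.sharks, table, window)
        for rec in records.values():
            if rec.days_detected:
                assert rec.r_max is not None and 0 < rec.r_max <= 1
                assert rec.r_min <= rec.r_max + 1e-12
            for value in rec.r_spatial.values():
                if value is not None:
                    assert 0.0 <= value <= 1.0
            for st_days in rec.days_detected_by_station.values():
                assert st_days <= rec.days_detected
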