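import datetime as dt

import numpy as np
import pandas as pd
import pytest

from aggresidence import occupancy as occ
from aggresidence.types import Shark, StudyWindow, TagDeployment, ValidationError


def day(*args):
    return dt.date(*args)


def make_shark(shark_id, start, sex="F", length=4.0):
    dep = TagDeployment(f"T-{shark_id}", shark_id, start)
    return Shark(shark_id, sex, length, [dep])


class TestMakeBins:
    def test_exact_division(self):
        window = StudyWindow(day(2012, 1, 1), day(2012, 3, 24))  # 84 days
        bins = occ.make_bins(window)
        assert len(bins) == 2
        assert not any(b.partial for b in bins)

    def test_partial_final_bin_flagged(self):
        window = StudyWindow(day(2012, 1, 1), day(2012, 4, 9))  # 100 days
        bins = occ.make_bins(window)
        assert len(bins) == 3
        assert bins[-1].partial and (bins[-1].end - bins[-1].start).days == 16

    def test_bins_tile_window(self):
        window = StudyWindow(day(2012, 1, 1), day(2013, 5, 7))
        bins = occ.make_bins(window)
        for a, b in zip(bins, bins[1:]):
            assert a.end == b.start
        assert bins[0].start == window.start
        assert bins[-1].end == window.end + dt.timedelta(days=1)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            occ.make_bins(StudyWindow(day(2012, 1, 1), day(2012, 2, 1)), width_days=0)


class TestBuildOccupancy:
    window = StudyWindow(day(2012, 1, 1), day(2012, 12, 31))

    def test_single_bin_occupied(self):
        bins = occ.make_bins(self.window)
        shark = make_shark("WS1", dt.datetime(2012, 1, 1, 8))
        target = bins[5]
        days = {"WS1": {target.start + dt.timedelta(days=3)}}
        records = occ.build_occupancy(days, [shark], bins, self.window)
        assert records.loc[records.bin_index == target.index, "occupied"].item() == 1
        assert records.loc[records.bin_index != target.index, "occupied"].eq(0).all()

    def test_no_records_before_tagging_bin(self):
        bins = occ.make_bins(self.window)
        shark = make_shark("WS1", dt.datetime(2012, 7, 1, 8))
        records = occ.build_occupancy({"WS1": set()}, [shark], bins, self.window)
        capture = self.window.local_date(shark.first_tagged)
        assert (records["bin_start"] >= capture).all()

    def test_lag_is_arithmetic_progression(self):
        bins = occ.make_bins(self.window)[:4]
        sharks = [
            make_shark("WS1", dt.datetime(2012, 1, 1, 8)),
            make_shark("WS2", dt.datetime(2012, 1, 1, 9), sex="M"),
        ]
        records = occ.build_occupancy({s.shark_id: set() for s in sharks}, sharks, bins, self.window)
        assert len(records) == 8
        for _, grp in records.groupby("shark_id"):
            lags = grp.sort_values("bin_index")["lag_days"].to_numpy()
            assert set(np.diff(lags)) == {42}

    def test_missing_capture_date_rejected(self):
        bins = occ.make_bins(self.window)
        bare = Shark("WS9", "U", None, [])
        with pytest.raises(ValidationError):
            occ.build_occupancy({}, [bare], bins, self.window)

    def test_occupancy_conserves_detection_information(self):
        bins = occ.make_bins(self.window)
        shark = make_shark("WS1", dt.datetime(2012, 1, 1, 8))
        days = {"WS1": {day(2012, 5, 5), day(2012, 9, 9)}}
        records = occ.build_occupancy(days, [shark], bins, self.window)
        assert records["occupied"].sum() >= 1


class TestCandidateModels:
    def test_acoustic_has_sixteen(self):
        specs = occ.candidate_models("acoustic")
        assert len(specs) == 16
        assert len(set(specs)) == 16

    def test_visual_has_eight(self):
        specs = occ.candidate_models("visual")
        assert len(specs) == 8
        assert len(set(specs)) == 8

    def test_all_contain_mandatory_smooths_implicitly(self):
        # fixed terms are optional; the empty spec is the smooths-only model
        specs = occ.candidate_models("acoustic")
        assert any(s.fixed_terms == () for s in specs)

    def test_unknown_dataset_rejected(self):
        with pytest.raises(ValidationError):
            occ.candidate_models("sonar")

    def test_disallowed_term_rejected(self):
        with pytest.raises(ValidationError):
            occ.ModelSpec("visual", ("inshore_effort",))


class TestSelectModel:
    def _fit(self, aic, terms=()):
        return occ.FitResult(spec=occ.ModelSpec("acoustic", terms), aic=aic, converged=True)

    def test_argmin(self):
        fits = [self._fit(100.0), self._fit(98.0, ("size",)), self._fit(105.0, ("sex",))]
        assert occ.select_model(fits).aic == 98.0

    def test_tie_prefers_fewer_terms(self):
        fits = [self._fit(98.0, ("sex", "size")), self._fit(98.0, ("size",))]
        assert occ.select_model(fits).spec.fixed_terms == ("size",)

    def test_no_converged_fit_errors(self):
        bad = occ.FitResult(spec=occ.ModelSpec("acoustic", ()), aic=np.inf, converged=False)
        with pytest.raises(ValidationError):
            occ.select_model([bad])


def _simulate_records(rng, n_sharks=30, n_years=3, peak_week=14.0, kappa=3.0,
                      baseline=0.75):
    """Direct binomial occupancy records with a known seasonal cycle."""
    window = StudyWindow(day(2011, 1, 1), day(2011 + n_years, 1, 1) - dt.timedelta(days=1))
    bins = occ.make_bins(window)
    sharks = [
        make_shark(f"WS{i:03d}", dt.datetime(2011, 1 + int(rng.integers(0, 3)), 1, 8),
                   sex=("F", "M")[int(rng.integers(0, 2))])
        for i in range(n_sharks)
    ]
    days = {}
    for s in sharks:
        detected = set()
        for b in bins:
            w = occ.week_of_year(b.midpoint)
            p = baseline * np.exp(kappa * (np.cos(2 * np.pi * (w - peak_week) / 52) - 1))
            if rng.random() < p:
                detected.add(b.start + dt.timedelta(days=int(rng.integers(0, 42))))
        days[s.shark_id] = detected
    records = occ.build_occupancy(days, sharks, bins, window)
    return records, window


class TestFitOccupancyModel:
    def test_recovers_seasonal_peak(self):
        rng = np.random.default_rng(5)
        records, _ = _simulate_records(rng, n_sharks=40, n_years=4)
        fit = occ.fit_occupancy_model(records, occ.ModelSpec("acoustic", ()),
                                      alpha=[10.0, 100.0, 100.0, 100.0])
        assert fit.converged
        assert abs(fit.peak_week - 14.0) <= 2.0 or abs(fit.peak_week - 14.0) >= 50.0

    def test_deterministic_and_shuffle_invariant_aic(self):
        rng = np.random.default_rng(6)
        records, _ = _simulate_records(rng, n_sharks=15, n_years=2)
        alpha = [10.0, 100.0, 100.0, 100.0]
        spec = occ.ModelSpec("acoustic", ())
        f1 = occ.fit_occupancy_model(records, spec, alpha=alpha)
        f2 = occ.fit_occupancy_model(records, spec, alpha=alpha)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-8)
        shuffled = records.sample(frac=1.0, random_state=1)
        f3 = occ.fit_occupancy_model(shuffled, spec, alpha=alpha)
        assert f1.aic == pytest.approx(f3.aic, abs=1e-6)

    def test_all_zero_outcome_degenerate_but_stable(self):
        rng = np.random.default_rng(7)
        records, _ = _simulate_records(rng, n_sharks=10, n_years=2, baseline=0.5)
        records = records.assign(occupied=0)
        fit = occ.fit_occupancy_model(records, occ.ModelSpec("acoustic", ()),
                                      alpha=[100.0] * 4)
        assert fit.params is not None
        p_hat = 1 / (1 + np.exp(-fit.params[0]))
        assert p_hat < 0.05


class TestRecaptureCurve:
    def _intercept_only_fit(self, beta0):
        spec = occ.ModelSpec("acoustic", ())

        def lp(week, lag, fixed=None):
            return np.full(np.atleast_1d(week).shape, beta0)

        return occ.FitResult(spec=spec, aic=0.0, converged=True,
                             params=np.array([beta0]), linear_predictor=lp)

    def test_zero_intercept_gives_half(self):
        fit = self._intercept_only_fit(0.0)
        dates = [day(2012, 1, 1) + dt.timedelta(days=i) for i in range(10)]
        curve = occ.recapture_curve(fit, {}, dates, day(2011, 12, 1))
        assert np.allclose(curve.to_numpy(), 0.5)

    def test_probabilities_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(8)
        records, window = _simulate_records(rng, n_sharks=15, n_years=2)
        fit = occ.fit_occupancy_model(records, occ.ModelSpec("acoustic", ()),
                                      alpha=[10.0, 100.0, 100.0, 100.0])
        curve = occ.recapture_curve(fit, {}, window.dates(), window.start)
        assert ((curve > 0) & (curve < 1)).all()

    def test_seasonal_component_continuous_at_year_boundary(self):
        """Cyclic constraint: the linear predictor matches across week 52→0."""
        rng = np.random.default_rng(9)
        records, _ = _simulate_records(rng, n_sharks=20, n_years=3)
        fit = occ.fit_occupancy_model(records, occ.ModelSpec("acoustic", ()),
                                      alpha=[10.0, 100.0, 100.0, 100.0])
        lag = np.array([200.0])
        eta_end = fit.linear_predictor(np.array([51.999]), lag, {})
        eta_start = fit.linear_predictor(np.array([0.001]), lag, {})
        assert abs(float(eta_end[0] - eta_start[0])) < 0.05

    def test_missing_profile_term_rejected(self):
        rng = np.random.default_rng(10)
        records, window = _simulate_records(rng, n_sharks=12, n_years=2)
        fit = occ.fit_occupancy_model(records, occ.ModelSpec("acoustic", ("size",)),
                                      alpha=[10.0, 100.0, 100.0, 100.0])
        with pytest.raises(ValidationError):
            occ.recapture_curve(fit, {}, window.dates()[:5], window.start)
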