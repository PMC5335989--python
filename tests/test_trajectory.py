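import dataclasses
import datetime
import math

import numpy as np
import pytest

from cherryripe import (
    DegenerateSeriesError,
    FittedCurve,
    IndexRecord,
    MaturityCriteria,
    ValidationError,
    aggregate_median,
    detect_ohd,
    fit_curve,
    logistic4,
    logistic4_derivative,
)
from cherryripe.trajectory import IndexSeries, read_series_csv, write_series_csv

TRUE_NAI = (-0.6, 0.8, 0.35, math.log(4.0 / 3.0) / 0.35)


def series_from(days, nai, ndvi=None, n=60):
    days = np.asarray(days, float)
    nai = np.asarray(nai, float)
    ndvi = nai if ndvi is None else np.asarray(ndvi, float)
    return IndexSeries(days=days, nai_median=nai, ndvi_median=ndvi, n_per_date=np.full(days.size, n))


def record(date, nai, fruit="F01", side="A", ndvi=0.0):
    return IndexRecord(date=date, fruit_id=fruit, side=side, nai=nai, ndvi=ndvi)


class TestAggregateMedian:
    def test_odd_count_median(self):
        recs = [record(0.0, v, fruit=f"F{i}") for i, v in enumerate([0.1, 0.2, 0.3])]
        series = aggregate_median(recs)
        assert series.nai_median[0] == pytest.approx(0.2)

    def test_even_count_uses_mean_of_central_pair(self):
        recs = [record(0.0, v, fruit=f"F{i}") for i, v in enumerate([0.1, 0.3])]
        assert aggregate_median(recs).nai_median[0] == pytest.approx(0.2)

    def test_counts_and_length(self):
        recs = [
            record(float(day), 0.1 * i / 60, fruit=f"F{i // 2}", side="AB"[i % 2])
            for day in (0, 2, 4)
            for i in range(60)
        ]
        series = aggregate_median(recs)
        assert len(series) == 3
        assert list(series.n_per_date) == [60, 60, 60]

    def test_calendar_dates_become_days_since_first(self):
        d0 = datetime.date(2012, 5, 29)
        recs = [record(d0 + datetime.timedelta(days=k), 0.01 * k) for k in (0, 2, 4)]
        series = aggregate_median(recs)
        assert list(series.days) == [0.0, 2.0, 4.0]
        assert series.start_date == d0
        assert series.day_to_date(2.0) == datetime.date(2012, 5, 31)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            aggregate_median([])


class TestFitCurve:
    def test_logistic_parameter_recovery_noise_free(self):
        t = np.arange(-8.0, 23.0, 2.0)  # 16 samples at 2-day cadence
        y = logistic4(t, *TRUE_NAI)
        series = series_from(t, y)
        curve = fit_curve(series, "nai")
        assert curve.family == "logistic4"
        assert curve.params == pytest.approx(TRUE_NAI, abs=1e-6)
        assert curve.fit_residual_rms < 1e-9

    def test_constant_series_is_degenerate(self):
        series = series_from([0, 2, 4, 6], [0.5, 0.5, 0.5, 0.5])
        with pytest.raises(DegenerateSeriesError):
            fit_curve(series, "nai")

    def test_cubic_family_interpolates_cubic_exactly(self):
        t = np.linspace(0, 10, 8)
        y = 0.1 - 0.02 * t + 0.003 * t**2 - 0.0001 * t**3
        curve = fit_curve(series_from(t, y), "nai", family="polynomial")
        assert curve.family == "polynomial"
        assert curve.fit_residual_rms < 1e-9

    def test_too_few_dates_rejected(self):
        with pytest.raises(ValidationError):
            fit_curve(series_from([0, 2, 4], [0.1, 0.2, 0.3]), "nai")


class TestDerivative:
    def test_logistic_at_midpoint_equals_quarter_rate_span(self):
        L, U, k, m = TRUE_NAI
        curve = FittedCurve("logistic4", TRUE_NAI, domain=(-10, 20))
        assert curve.derivative(m) == pytest.approx(k * (U - L) / 4.0)

    def test_constant_polynomial_has_zero_derivative(self):
        curve = FittedCurve("polynomial", (0.3,), domain=(0, 10))
        assert curve.derivative(5.0) == 0.0

    def test_logistic_plateau_entry_slope(self):
        # oracle: closed form k (y-L)(U-y)/(U-L) at t = 13
        L, U, k, m = TRUE_NAI
        curve = FittedCurve("logistic4", TRUE_NAI, domain=(-10, 20))
        y = curve.value(13.0)
        expected = k * (y - L) * (U - y) / (U - L)
        assert curve.derivative(13.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0067, abs=2e-4)

    def test_out_of_domain_requires_extend_flag(self):
        curve = FittedCurve("logistic4", TRUE_NAI, domain=(0, 10))
        with pytest.raises(ValidationError):
            curve.value(50.0)
        assert np.isfinite(curve.value(50.0, extend=True))


class TestDetectOhd:
    def test_reference_trajectory_fires_at_day_13(self, reference_curves, criteria):
        nai_curve, ndvi_curve = reference_curves
        det = detect_ohd(nai_curve, ndvi_curve, criteria)
        assert det.detected
        assert det.t_ohd == pytest.approx(13.0, abs=det.grid_step_days)
        assert criteria.nai_ohd_range[0] <= det.nai_at_ohd <= criteria.nai_ohd_range[1]
        assert criteria.ndvi_ohd_range[0] <= det.ndvi_at_ohd <= criteria.ndvi_ohd_range[1]
        assert abs(det.nai_slope_at_ohd) <= criteria.derivative_epsilon
        assert "ndvi_range" in det.binding  # the chlorophyll zero crossing sets the date

    def test_ndvi_permanently_negative_flags_ndvi(self, criteria):
        nai_curve = FittedCurve("logistic4", TRUE_NAI, domain=(-8, 18))
        low_ndvi = FittedCurve("logistic4", (-0.9, -0.1, 0.2265, 13.0), domain=(-8, 18))
        det = detect_ohd(nai_curve, low_ndvi, criteria)
        assert det.status == "not_reached"
        assert det.first_unmet == "ndvi_range"

    def test_zero_epsilon_never_fires_on_a_logistic(self, reference_curves, criteria):
        nai_curve, ndvi_curve = reference_curves
        crit = dataclasses.replace(criteria, derivative_epsilon=0.0)
        det = detect_ohd(nai_curve, ndvi_curve, crit)
        assert det.status == "not_reached"
        assert det.first_unmet == "nai_derivative"

    @pytest.mark.parametrize("eps_pair", [(0.005, 0.01), (0.01, 0.05), (0.0067, 0.02)])
    def test_monotone_in_epsilon(self, reference_curves, criteria, eps_pair):
        nai_curve, ndvi_curve = reference_curves
        small, large = eps_pair
        det_small = detect_ohd(nai_curve, ndvi_curve, dataclasses.replace(criteria, derivative_epsilon=small))
        det_large = detect_ohd(nai_curve, ndvi_curve, dataclasses.replace(criteria, derivative_epsilon=large))
        if det_small.detected:
            assert det_large.detected
            assert det_large.t_ohd <= det_small.t_ohd

    def test_invariant_under_date_translation(self, criteria):
        recs = []
        for day in np.arange(-8.0, 18.1, 2.0):
            from cherryripe import reference_trajectory

            nai, ndvi = reference_trajectory(t=day)
            recs.append(IndexRecord(date=day, fruit_id="F01", side="A", nai=nai, ndvi=ndvi))
        shifted = [
            IndexRecord(date=float(r.date) + 100.0, fruit_id=r.fruit_id, side=r.side, nai=r.nai, ndvi=r.ndvi)
            for r in recs
        ]
        det_a = _detect_from_records(recs, criteria)
        det_b = _detect_from_records(shifted, criteria)
        assert det_b.t_ohd == pytest.approx(det_a.t_ohd, abs=1e-9)

    def test_halving_grid_step_moves_result_by_at_most_one_step(self, reference_curves, criteria):
        nai_curve, ndvi_curve = reference_curves
        coarse = detect_ohd(nai_curve, ndvi_curve, criteria, grid_step_days=0.5)
        fine = detect_ohd(nai_curve, ndvi_curve, criteria, grid_step_days=0.25)
        assert abs(coarse.t_ohd - fine.t_ohd) <= 0.5 + 1e-9

    def test_grid_search_matches_closed_form_plateau_time(self):
        # on a bare logistic (other criteria wide open), the earliest time with
        # |y'| <= eps past the inflection has a closed form from inverting the
        # derivative expression
        L, U, k, m = TRUE_NAI
        eps = 0.01
        c = eps * (U - L) / k
        y_star = ((L + U) + math.sqrt((U - L) ** 2 - 4.0 * c)) / 2.0
        t_star = m - math.log((U - y_star) / (y_star - L)) / k
        curve = FittedCurve("logistic4", TRUE_NAI, domain=(m, m + 40.0))
        wide = MaturityCriteria(
            ndvi_ohd_range=(-1.0, 1.0), nai_ohd_range=(-1.0, 1.0), derivative_epsilon=eps
        )
        det = detect_ohd(curve, curve, wide, grid_step_days=0.25)
        assert det.detected
        assert det.t_ohd == pytest.approx(t_star, abs=0.25)


def _detect_from_records(records, criteria):
    series = aggregate_median(records)
    nai_curve = fit_curve(series, "nai")
    ndvi_curve = fit_curve(series, "ndvi")
    return detect_ohd(nai_curve, ndvi_curve, criteria)


class TestSeriesCsv:
    def test_round_trip(self, tmp_path, noise_free_series):
        path = tmp_path / "series.csv"
        write_series_csv(noise_free_series, path)
        back = read_series_csv(path)
        assert back.days == pytest.approx(noise_free_series.days)
        assert back.nai_median == pytest.approx(noise_free_series.nai_median)
        assert list(back.n_per_date) == list(noise_free_series.n_per_date)


class TestCriteriaConfig:
    def test_yaml_round_trip(self, tmp_path, criteria):
        path = tmp_path / "crit.yaml"
        criteria.to_yaml(path)
        assert MaturityCriteria.from_yaml(path) == criteria

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "crit.yaml"
        path.write_text("derivative_epsilon: 0.01\nbogus_key: 1\n")
        from cherryripe import ConfigurationError

        with pytest.raises(ConfigurationError):
            MaturityCriteria.from_yaml(path)

    def test_disordered_range_rejected(self):
        with pytest.raises(ValidationError):
            MaturityCriteria(nai_ohd_range=(0.8, 0.7))
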