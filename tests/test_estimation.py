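"""Session reduction: averaging windows, HR-VO2 fit, VO2max extrapolation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from steptest4all.errors import (
    DegenerateFitError,
    InsufficientDataError,
    ValidationError,
)
from steptest4all.estimation import (
    PhysioTimeSeries,
    StagePoint,
    analyze_session,
    estimate_vo2max,
    fit_hr_vo2,
    recovery_summary,
    resting_values,
    stage_endpoints,
)


def ols_oracle(x, y):
    """Normal-equations least squares (centered sums), independent of the fit path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    slope = (dx * dy).sum() / (dx * dx).sum()
    intercept = y.mean() - slope * x.mean()
    ss_res = ((y - intercept - slope * x) ** 2).sum()
    ss_tot = (dy * dy).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return slope, intercept, r2


class TestSeriesValidation:
    def test_non_monotone_time_rejected(self, make_session):
        ts = make_session()
        df = ts.df.copy()
        df.loc[3, "time_s"] = df.loc[1, "time_s"]
        with pytest.raises(ValidationError, match="increasing"):
            PhysioTimeSeries(df)

    def test_phase_order_enforced(self, make_session):
        df = make_session().df.copy()
        df.loc[len(df) - 1, "phase"] = "stage_1"  # stage after recovery
        with pytest.raises(ValidationError, match="order"):
            PhysioTimeSeries(df)

    def test_missing_vo2_outside_recovery_rejected(self, make_session):
        df = make_session().df.copy()
        df.loc[10, "vo2_mlkgmin"] = math.nan  # rest-phase gap
        with pytest.raises(ValidationError, match="recovery"):
            PhysioTimeSeries(df)

    def test_nan_in_recovery_accepted(self, make_session):
        ts = make_session()
        assert ts.df[ts.df["phase"] == "recovery"]["vo2_mlkgmin"].isna().all()


class TestRestingValues:
    def test_constant_rest(self, make_session):
        hr, vo2 = resting_values(make_session(rest_hr=70.0, rest_vo2=3.5))
        assert hr == pytest.approx(70.0)
        assert vo2 == pytest.approx(3.5)

    def test_linear_ramp_averages_to_midpoint(self, make_session):
        # hr rises 60 -> 80 over the final 61 samples (t = 60 .. 120)
        def ramp(t):
            return 60.0 + (t - 60) / 3.0 if t >= 60 else 60.0

        ts = make_session(rest_hr=ramp, rest_dur=121)
        hr, _ = resting_values(ts)
        assert hr == pytest.approx(70.0)

    def test_short_rest_rejected(self, make_session):
        with pytest.raises(InsufficientDataError, match="rest"):
            resting_values(make_session(rest_dur=45))


class TestStageEndpoints:
    def test_constant_stages(self, make_session):
        pts = stage_endpoints(make_session(stage_hr=(100.0, 115.0, 130.0)))
        assert [p.hr for p in pts] == pytest.approx([100.0, 115.0, 130.0])
        assert [p.stage_index for p in pts] == [1, 2, 3]
        assert [p.cadence for p in pts] == pytest.approx([15.0, 17.5, 20.0])

    def test_linear_stage_uses_final_six_samples(self, make_session):
        # within-stage hr = 100 + j at 1 Hz; window holds j = 54..59
        ts = make_session(stage_hr=(lambda j: 100.0 + j, 115.0, 130.0))
        pts = stage_endpoints(ts)
        assert pts[0].hr == pytest.approx(np.mean([154, 155, 156, 157, 158, 159]))

    def test_no_stage_rejected(self, make_session):
        df = make_session().df
        rest_only = df[df["phase"] == "rest"]
        with pytest.raises(InsufficientDataError, match="stage"):
            stage_endpoints(PhysioTimeSeries(rest_only))


class TestRecoverySummary:
    def test_difference_of_end_and_minute_average(self, make_session):
        ts = make_session(stage_hr=(140.0, 150.0, 165.0),
                          recovery_hr=lambda t: 128.0)
        rec = recovery_summary(ts)
        assert rec.hr_end == pytest.approx(165.0)
        assert rec.hr_60 == pytest.approx(128.0)
        assert rec.hrr60 == pytest.approx(37.0)
        assert not rec.flagged

    def test_flat_recovery_gives_zero_not_flagged(self, make_session):
        ts = make_session(stage_hr=(140.0, 150.0, 165.0),
                          recovery_hr=lambda t: 165.0)
        rec = recovery_summary(ts)
        assert rec.hrr60 == pytest.approx(0.0)
        assert not rec.flagged

    def test_rising_recovery_is_flagged(self, make_session):
        ts = make_session(stage_hr=(140.0, 150.0, 165.0),
                          recovery_hr=lambda t: 170.0)
        assert recovery_summary(ts).flagged

    def test_exponential_recovery_matches_closed_form(self, make_session):
        # hr(t) = 80 + (170 - 80) exp(-t/60); window mean over t = 55..60 s
        decay = lambda t: 80.0 + 90.0 * math.exp(-t / 60.0)
        ts = make_session(stage_hr=(150.0, 160.0, 170.0), recovery_hr=decay)
        expected_hr60 = np.mean([decay(t) for t in range(55, 61)])
        rec = recovery_summary(ts)
        assert rec.hr_60 == pytest.approx(expected_hr60)
        assert rec.hrr60 == pytest.approx(170.0 - expected_hr60)

    def test_instantaneous_end_mode(self, make_session):
        ts = make_session(stage_hr=(140.0, 150.0, lambda j: 160.0 + 0.1 * j),
                          recovery_hr=lambda t: 120.0)
        stage_avg = recovery_summary(ts).hr_end
        instant = recovery_summary(ts, hr_end_mode="instantaneous").hr_end
        assert instant == pytest.approx(160.0 + 0.1 * 59)
        assert stage_avg < instant  # average of the last 6 ramping samples

    def test_short_recovery_rejected(self, make_session):
        with pytest.raises(InsufficientDataError, match="recovery"):
            recovery_summary(make_session(recovery_dur=50))

    def test_hrr60_invariant_to_time_shift_and_hr_offset(self, make_session):
        ts = make_session(stage_hr=(140.0, 150.0, 165.0),
                          recovery_hr=lambda t: 130.0 - 0.1 * t)
        base = recovery_summary(ts).hrr60
        shifted = ts.df.copy()
        shifted["time_s"] += 1234.5
        assert recovery_summary(PhysioTimeSeries(shifted)).hrr60 == pytest.approx(base)
        offset = ts.df.copy()
        offset["hr_bpm"] += 12.0
        assert recovery_summary(PhysioTimeSeries(offset)).hrr60 == pytest.approx(base)


class TestFitAndExtrapolation:
    def test_collinear_points_fit_exactly(self):
        pts = [StagePoint(k, 15 + 2.5 * (k - 1), 100.0 + 10 * k, 10.0 + 2 * k)
               for k in (1, 2, 3)]
        fit = fit_hr_vo2((90.0, 8.0), pts)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(8.0 - 0.2 * 90.0)
        assert fit.n_points == 4

    def test_four_point_fit_matches_normal_equations(self):
        hr = [80.0, 110.0, 125.0, 140.0]
        vo2 = [4.0, 14.0, 18.5, 24.0]
        pts = [StagePoint(k, 15.0, h, v)
               for k, (h, v) in enumerate(zip(hr[1:], vo2[1:]), start=1)]
        fit = fit_hr_vo2((hr[0], vo2[0]), pts)
        slope, intercept, r2 = ols_oracle(hr, vo2)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)
        assert fit.r2 == pytest.approx(r2)

    def test_exclude_rest_switch(self):
        pts = [StagePoint(k, 15.0, 100.0 + 10 * k, 10.0 + 2.0 * k + (k == 2))
               for k in (1, 2, 3)]
        with_rest = fit_hr_vo2((60.0, 3.0), pts)
        without = fit_hr_vo2((60.0, 3.0), pts, include_rest=False)
        assert with_rest.n_points == 4
        assert without.n_points == 3
        assert with_rest.slope != pytest.approx(without.slope)

    def test_too_few_stage_points_rejected(self):
        pts = [StagePoint(1, 15.0, 100.0, 10.0), StagePoint(2, 17.5, 110.0, 12.0)]
        with pytest.raises(InsufficientDataError):
            fit_hr_vo2((70.0, 3.5), pts)

    def test_zero_hr_variance_rejected(self):
        pts = [StagePoint(k, 15.0, 100.0, 10.0 + k) for k in (1, 2, 3)]
        with pytest.raises(DegenerateFitError):
            fit_hr_vo2((100.0, 3.5), pts)

    def test_line_evaluation_at_hrmax(self):
        from steptest4all.estimation import SubmaximalFit

        fit = SubmaximalFit(slope=0.25, intercept=-5.0, r2=0.99, n_points=4)
        assert estimate_vo2max(fit, 194.0) == pytest.approx(43.5)

    def test_interpolation_identity_and_warning(self):
        pts = [StagePoint(k, 15.0, 100.0 + 10 * k, 10.0 + 2 * k) for k in (1, 2, 3)]
        fit = fit_hr_vo2((90.0, 8.0), pts)
        with pytest.warns(UserWarning, match="interpolation"):
            value = estimate_vo2max(fit, 120.0, max_observed_hr=130.0)
        assert value == pytest.approx(14.0)  # the stage-2 point's VO2

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=60, max_value=200),
                st.floats(min_value=2, max_value=60),
            ),
            min_size=4,
            max_size=10,
            unique_by=lambda p: round(p[0], 3),
        )
    )
    def test_fit_matches_oracle_on_random_point_sets(self, points):
        hr = [p[0] for p in points]
        vo2 = [p[1] for p in points]
        pts = [StagePoint(k, 15.0, h, v)
               for k, (h, v) in enumerate(zip(hr[1:], vo2[1:]), start=1)]
        fit = fit_hr_vo2((hr[0], vo2[0]), pts)
        slope, intercept, _ = ols_oracle(hr, vo2)
        assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)


class TestAnalyzeSession:
    def test_full_reduction_on_linear_session(self, make_session):
        # VO2 = 0.3 * (HR - 70) + 3.5 exactly; extrapolation is then exact
        stage_hr = (110.0, 130.0, 150.0)
        stage_vo2 = tuple(3.5 + 0.3 * (h - 70.0) for h in stage_hr)
        ts = make_session(stage_hr=stage_hr, stage_vo2=stage_vo2,
                          recovery_hr=lambda t: 100.0)
        report = analyze_session(ts, age=20)
        assert report.hrmax == pytest.approx(194.0)
        assert report.fit.r2 == pytest.approx(1.0)
        assert report.vo2max == pytest.approx(3.5 + 0.3 * (194.0 - 70.0))
        assert report.recovery.hrr60 == pytest.approx(50.0)
        assert report.extrapolated

    def test_age_or_hrmax_required(self, make_session):
        with pytest.raises(ValidationError):
            analyze_session(make_session())
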