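import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import intertidal.dynamics as dyn
from intertidal.io import TransectProfile, ValidationError
from intertidal.synth import default_dates, gen_marker_series, gen_rset_series


class TestRsetTrend:
    def test_noiseless_rate(self):
        df = gen_rset_series({"B1": 0.0}, a_true=10.0, b_true=0.0,
                             dates=default_dates(5))
        trend = dyn.fit_rset_trend(df)
        assert trend.loc["B1", "rate_mm_yr"] == pytest.approx(10.0)
        assert trend.loc["B1", "r_squared"] == pytest.approx(1.0)

    def test_sign_convention(self):
        """Pins sticking out more over time = surface loss = negative rate."""
        df = gen_rset_series({"B1": 0.0}, a_true=10.0, b_true=0.0,
                             dates=default_dates(5))
        df["distance_mm"] = 1000.0 - df["distance_mm"]
        trend = dyn.fit_rset_trend(df)
        assert trend.loc["B1", "rate_mm_yr"] == pytest.approx(-10.0)

    def test_incomplete_occasion_dropped(self):
        df = gen_rset_series({"B1": 0.0}, 10.0, 0.0, dates=default_dates(5))
        last = df["date"].max()
        df = df[~((df.date == last) & (df.pin == 9) & (df.direction == 4))]
        with pytest.warns(UserWarning, match="incomplete"):
            trend = dyn.fit_rset_trend(df)
        assert trend.loc["B1", "n_occasions"] == 4

    def test_noisy_rate_within_two_se(self):
        df = gen_rset_series({"B1": 20.0}, a_true=8.0, b_true=0.004,
                             dates=default_dates(8), noise_sd_mm=2.0, seed=1)
        trend = dyn.fit_rset_trend(df)
        truth = 8.0 * np.exp(-0.004 * 20.0)
        assert abs(trend.loc["B1", "rate_mm_yr"] - truth) < 2 * trend.loc[
            "B1", "stderr"] + 1e-9


class TestAccretion:
    def test_two_occasions(self):
        df = pd.DataFrame({
            "station_id": ["s", "s"],
            "date": pd.to_datetime(["2020-01-01", "2021-01-01"]),
            "core_id": [1, 1],
            "depth_mm": [0.0, 12.0 * 366 / 365.25],
        })
        acc = dyn.accretion_rate(df)
        assert acc.loc["s", "accretion_mm_yr"] == pytest.approx(12.0)

    def test_three_cores_averaged_with_deployment_anchor(self):
        df = pd.DataFrame({
            "station_id": ["s"] * 3,
            "date": pd.to_datetime(["2021-01-01"] * 3),
            "core_id": [1, 2, 3],
            "depth_mm": [10.0, 12.0, 14.0],
        })
        acc = dyn.accretion_rate(df, deployment="2020-01-01")
        assert acc.loc["s", "accretion_mm_yr"] == pytest.approx(
            12.0 / (366 / 365.25))

    def test_single_occasion_without_anchor_errors(self):
        df = pd.DataFrame({
            "station_id": ["s"],
            "date": pd.to_datetime(["2021-01-01"]),
            "core_id": [1],
            "depth_mm": [10.0],
        })
        with pytest.raises(ValidationError):
            dyn.accretion_rate(df)


class TestAccretionRegression:
    def test_exact_line(self):
        x = np.array([5.0, 10, 15, 20, 25])
        fit = dyn.fit_accretion_regression(x, 0.4 * x + 1.0)
        assert fit.slope == pytest.approx(0.4)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_regressor_singular(self):
        with pytest.raises(ValidationError):
            dyn.fit_accretion_regression([5.0, 5, 5], [1.0, 2, 3])

    def test_too_few_pairs(self):
        with pytest.raises(ValidationError):
            dyn.fit_accretion_regression([1.0, 2], [1.0, 2])

    @pytest.mark.parametrize(
        "slope,intercept,x,expected",
        [(1.0, 0.0, 3.3, 3.3), (0.5, 2.0, 10.0, 7.0)],
    )
    def test_predict(self, slope, intercept, x, expected):
        fit = dyn.LinearFit(slope, intercept, 1.0, 0.0, 0.0, 5)
        assert dyn.predict_elev_change(fit, x) == pytest.approx(expected)


class TestExponentialFit:
    def test_exact_recovery(self):
        e = np.array([-15.0, 10, 35, 60, 85, 110, 150])
        r = 8.0 * np.exp(-0.004 * e)
        res = dyn.SurfaceElevationModel(e, r).fit()
        assert res.a == pytest.approx(8.0, rel=1e-6)
        assert res.b == pytest.approx(0.004, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_rates_limit(self):
        e = np.array([0.0, 50, 100])
        res = dyn.SurfaceElevationModel(e, np.full(3, 5.0)).fit()
        assert res.b == pytest.approx(0.0, abs=1e-10)
        assert res.a == pytest.approx(5.0)

    def test_loglinear_start_is_exact_on_exponential_data(self):
        e = np.array([0.0, 40, 80, 120])
        r = 7.0 * np.exp(-0.003 * e)
        a0, b0 = dyn.SurfaceElevationModel._loglinear_start(e, r)
        assert a0 == pytest.approx(7.0) and b0 == pytest.approx(0.003)

    def test_nonpositive_rates_excluded(self):
        e = np.array([0.0, 50, 100, 150])
        r = np.array([8.0, 5.0, 3.0, -1.0])
        with pytest.warns(UserWarning, match="non-positive"):
            res = dyn.SurfaceElevationModel(e, r).fit()
        assert res.nobs == 3


class TestThresholdCalibration:
    def test_closed_form(self, threshold_model):
        assert threshold_model.b == pytest.approx(3.4987e-3, rel=1e-4)
        assert threshold_model.a == pytest.approx(7.7238, rel=1e-4)

    def test_equal_rates_give_flat_law(self):
        res = dyn.calibrate_from_thresholds(0.0, 5.0, 100.0, 5.0)
        assert res.b == 0.0 and res.a == pytest.approx(5.0)

    def test_identity_on_anchors(self, threshold_model):
        """calibrate_from_thresholds ∘ critical_slr fixes both anchors."""
        assert float(threshold_model.critical_slr(150.0)) == pytest.approx(
            4.57, abs=1e-12)
        assert float(threshold_model.critical_slr(-15.0)) == pytest.approx(
            8.14, abs=1e-12)

    def test_invalid_anchors(self):
        with pytest.raises(ValidationError):
            dyn.calibrate_from_thresholds(0.0, -1.0, 100.0, 5.0)
        with pytest.raises(ValidationError):
            dyn.calibrate_from_thresholds(50.0, 5.0, 50.0, 6.0)


class TestSimulation:
    def test_equilibrium_step_is_fixed_point(self, threshold_model):
        e = 40.0
        s = float(threshold_model.critical_slr(e))
        assert dyn.annual_step(e, threshold_model.a, threshold_model.b, s) == (
            pytest.approx(e))

    def test_step_without_feedback(self):
        assert dyn.annual_step(0.0, 10.0, 0.0, 0.0) == pytest.approx(1.0)

    def test_step_size_decreasing_in_elevation(self, threshold_model):
        e = np.linspace(-50, 200, 100)
        gain = dyn.annual_step(e, threshold_model.a, threshold_model.b, 0.0) - e
        assert np.all(np.diff(gain) < 0)

    def test_trajectory_shape_and_start(self, threshold_model):
        traj = threshold_model.simulate(150.0, 16.0)
        assert traj.shape == (81,)
        assert traj[0] == 150.0

    def test_flat_at_critical_rate(self, threshold_model):
        s = float(threshold_model.critical_slr(60.0))
        traj = threshold_model.simulate(60.0, s)
        np.testing.assert_allclose(traj, 60.0, atol=1e-9)

    def test_matches_refined_integrator(self, threshold_model):
        """dt = 0.01 yr forward integration agrees within 1.5 cm."""
        a, b = threshold_model.a, threshold_model.b

        def fine(e0, s):
            e, dt = e0, 0.01
            for _ in range(8000):
                e += (a * np.exp(-b * e) - s) / 10.0 * dt
            return e

        for e0 in (-15.0, 60.0, 150.0):
            for s in (2.0, 8.0, 16.0):
                coarse = threshold_model.simulate(e0, s)[-1]
                assert abs(coarse - fine(e0, s)) < 1.5

    def test_monotone_convergence_no_oscillation(self, threshold_model):
        for s in np.arange(2.0, 16.01, 0.25):
            for e0 in (-15.0, 60.0, 150.0):
                traj = threshold_model.simulate(float(e0), float(s))
                diffs = np.diff(traj)
                assert np.all(diffs >= 0) or np.all(diffs <= 0)

    def test_scenario_monotonicity(self, threshold_model):
        finals = [threshold_model.simulate(150.0, float(s))[-1]
                  for s in np.arange(2.0, 16.01, 0.5)]
        assert np.all(np.diff(finals) < 0)
        finals_e0 = [threshold_model.simulate(float(e0), 10.0)[-1]
                     for e0 in np.linspace(-15, 150, 12)]
        assert np.all(np.diff(finals_e0) > 0)

    def test_endpoint_sign_matches_critical_slr(self, threshold_model):
        for e0 in (-15.0, 35.0, 110.0):
            crit = float(threshold_model.critical_slr(e0))
            for s in (crit - 1.0, crit + 1.0):
                final = threshold_model.simulate(e0, s)[-1]
                assert np.sign(final - e0) == np.sign(crit - s)


class TestEquilibrium:
    def test_closed_form(self, threshold_model):
        estar = threshold_model.equilibrium(16.0)
        assert estar == pytest.approx(
            np.log(threshold_model.a / 16.0) / threshold_model.b)
        assert estar == pytest.approx(-208.16, abs=0.05)

    def test_s_equals_a_gives_zero(self, threshold_model):
        assert threshold_model.equilibrium(threshold_model.a) == pytest.approx(0.0)

    def test_long_run_convergence(self, threshold_model):
        final = threshold_model.simulate(150.0, 16.0, 2020, 4020)[-1]
        assert abs(final - threshold_model.equilibrium(16.0)) < 0.01

    def test_flat_law_undefined(self):
        res = dyn.calibrate_from_thresholds(0.0, 5.0, 100.0, 5.0)
        assert np.isnan(res.equilibrium(3.0))


class TestZoneExtent:
    def test_all_above_floor(self, sj_profile):
        ext = dyn.zone_extent(sj_profile, -15.0, seaward_edge_m=0.0)
        assert ext.n_segments == 1
        assert ext.total_width_m == pytest.approx(680.03)

    def test_interpolated_crossing(self):
        p = TransectProfile(("a", "b"), [0.0, 100.0], [10.0, -30.0])
        ext = dyn.zone_extent(p, -15.0)
        assert ext.total_width_m == pytest.approx(62.5)
        assert ext.segments[0] == (0.0, 62.5)

    def test_all_below_floor(self):
        p = TransectProfile(("a", "b"), [0.0, 100.0], [-40.0, -30.0])
        ext = dyn.zone_extent(p, -15.0)
        assert ext.n_segments == 0 and ext.total_width_m == 0.0

    def test_disjoint_segments(self):
        p = TransectProfile(
            tuple("abcd"), [0.0, 10.0, 20.0, 30.0], [0.0, -40.0, -40.0, 0.0])
        ext = dyn.zone_extent(p, -15.0)
        assert ext.n_segments == 2
        assert ext.total_width_m == pytest.approx(
            sum(b - a for a, b in ext.segments))

    @given(st.floats(min_value=-50, max_value=50))
    def test_width_fraction_bounded_for_descending_floor(self, e_min):
        p2020 = TransectProfile(tuple("ab"), [0.0, 100.0], [60.0, 150.0])
        p2100 = TransectProfile(tuple("ab"), [0.0, 100.0], [55.0, 140.0])
        if e_min > 55.0:
            return
        frac = dyn.zone_width_fraction(p2020, p2100, e_min)
        assert 0.0 <= frac <= 1.0


class TestEndpointCalibration:
    def test_round_trip_from_threshold_model(self, threshold_model):
        endpoint = float(threshold_model.simulate(150.0, 16.0)[-1])
        res = dyn.calibrate_from_endpoint(-15.0, 8.14, 150.0, 16.0, endpoint)
        assert res.b == pytest.approx(threshold_model.b, rel=1e-8)
        assert res.a == pytest.approx(threshold_model.a, rel=1e-8)

    def test_unbracketed_endpoint_rejected(self):
        with pytest.raises(ValidationError):
            dyn.calibrate_from_endpoint(-15.0, 8.14, 150.0, 16.0, 500.0)
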