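"""Residence-time fitting, arrival detection, velocity, label fractions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinetrace.isotope import ExcessSeries
from pinetrace.kinetics import (ArrivalLag, ExponentialDecayModel,
                                cumulative_released, detect_arrival,
                                fraction_allocated, peak_time,
                                transport_velocity)

TIMES = np.array([0.03125, 1.0, 2.0, 3.0, 7.0, 14.0])


def _decay_series(n0, tau, times=TIMES):
    return ExcessSeries("needle", "m1", times, n0 * np.exp(-times / tau))


@pytest.mark.parametrize("tau", [3.4, 9.3])
def test_exact_recovery_on_noiseless_decay(tau):
    res = ExponentialDecayModel(_decay_series(30.0, tau)).fit()
    assert res.tau == pytest.approx(tau, abs=1e-6)
    assert res.n0 == pytest.approx(30.0, rel=1e-6)
    assert abs(res.tau * res.lam - 1.0) <= 1e-12


@settings(max_examples=30, derandomize=True)
@given(st.floats(min_value=0.5, max_value=50.0))
def test_exact_recovery_for_any_residence_time(tau):
    times = np.array([0.03125, 1.0, 2.0, 3.0, 7.0, 14.0, 47.0])
    res = ExponentialDecayModel(_decay_series(12.0, tau, times)).fit()
    assert res.tau == pytest.approx(tau, rel=1e-6)


def test_tau_invariant_under_series_rescaling():
    res1 = ExponentialDecayModel(_decay_series(30.0, 3.4)).fit()
    res2 = ExponentialDecayModel(_decay_series(30.0, 3.4).scaled(7.0)).fit()
    assert res2.tau == pytest.approx(res1.tau, rel=1e-9)
    assert res2.n0 == pytest.approx(7.0 * res1.n0, rel=1e-9)


def test_pre_peak_points_excluded_from_fit():
    times = np.array([0.03125, 1.0, 2.0, 3.0, 7.0, 14.0])
    vals = 30.0 * np.exp(-(times - 1.0) / 3.4)
    vals[0] = 5.0  # still rising at the first sample
    res = ExponentialDecayModel(
        ExcessSeries("needle", "m1", times, vals)).fit()
    assert res.n_points == 5
    assert res.tau == pytest.approx(3.4, rel=1e-6)


def test_non_decaying_series_is_flagged():
    from pinetrace.kinetics import NonDecayingSeriesError
    times = np.array([0.03125, 1.0, 2.0, 3.0])
    grow = ExcessSeries("needle", "m1", times, np.array([1.0, 1.2, 1.5, 2.0]))
    with pytest.raises((NonDecayingSeriesError, ValueError)):
        ExponentialDecayModel(grow, from_peak=False).fit()


def test_fit_diagnostics_and_summary():
    res = ExponentialDecayModel(_decay_series(30.0, 3.4)).fit()
    assert res.rss == pytest.approx(0.0, abs=1e-12)
    text = res.summary()
    assert "tau" in text and "lambda" in text


class TestDetectArrival:
    def test_step_at_three_days(self):
        t = np.array([-1.0, 1.0, 2.0, 3.0, 5.0, 7.0])
        v = np.array([0.0, 0.0, 0.0, 10.0, 10.0, 10.0])
        s = ExcessSeries("soil_pore_co2", "m1", t, v)
        lag = detect_arrival(s, baseline_mean=0.0, baseline_sd=1.0)
        assert lag.detected and lag.lag_days == 3.0

    def test_all_baseline_series_yields_no_arrival(self):
        t = np.array([-1.0, 1.0, 2.0, 3.0])
        s = ExcessSeries("soil_pore_co2", "m1", t, np.zeros(4))
        lag = detect_arrival(s, 0.0, 1.0)
        assert not lag.detected and lag.lag_days is None

    def test_transient_spike_rejected_by_persistence(self):
        t = np.array([-1.0, 1.0, 2.0, 3.0, 5.0])
        v = np.array([0.0, 8.0, 0.0, 10.0, 10.0])
        lag = detect_arrival(ExcessSeries("x", "m1", t, v), 0.0, 1.0)
        assert lag.lag_days == 3.0

    def test_simulator_injected_delay_recovered(self, default_campaign):
        """The treatment-level arrival on the gas schedule matches the
        scenario's injected arrival days (1.5 / 1.5 / 3)."""
        from pinetrace import pipeline
        scenario, table, truth = default_campaign
        ts = pipeline.transport_summary(table)
        for trt in scenario.treatments:
            lag = ts.loc[ts["treatment"] == trt, "arrival_lag_d"].iloc[0]
            assert lag == pytest.approx(truth.arrival_day(trt))


class TestTransportVelocity:
    def test_height_over_lag_arithmetic(self):
        assert transport_velocity(72.0, 3.0).velocity_cm_d == pytest.approx(24.0)
        assert transport_velocity(72.0, 1.5).velocity_cm_d == pytest.approx(48.0)

    def test_velocity_times_lag_is_height(self):
        v = transport_velocity(67.3, 2.25)
        assert v.velocity_cm_d * v.lag_days == pytest.approx(67.3, rel=1e-12)

    def test_zero_lag_rejected(self):
        with pytest.raises(ValueError):
            transport_velocity(72.0, 0.0)
        with pytest.raises(ValueError):
            transport_velocity(72.0, ArrivalLag(None, 0.0, 3.0, False))


class TestFractionAllocated:
    def test_needle_series_against_itself_is_one_at_45min(self):
        s = _decay_series(30.0, 3.4)
        frac = fraction_allocated(s, s.values[0])
        assert frac.values[0] == pytest.approx(1.0)

    def test_zero_series_gives_zero_fractions(self):
        s = ExcessSeries("fine_root", "m1", TIMES, np.zeros_like(TIMES))
        assert np.all(fraction_allocated(s, 30.0).values == 0.0)

    def test_fractions_are_dose_invariant(self):
        s = _decay_series(30.0, 3.4)
        f1 = fraction_allocated(s, 30.0)
        f2 = fraction_allocated(s.scaled(2.0), 60.0)
        np.testing.assert_allclose(f1.values, f2.values, rtol=1e-12)

    def test_root_fraction_recovers_configured_transfer(self, default_campaign):
        """By day 14 the root fraction approaches the scenario's transfer
        fraction (the ramp has saturated)."""
        from pinetrace import pipeline
        scenario, table, _ = default_campaign
        fr = pipeline.allocation_fractions(table)
        by_trt = fr.groupby("treatment")["fine_root_fraction"].mean()
        for trt, p in scenario.treatments.items():
            assert by_trt[trt] == pytest.approx(
                p.root_transfer_fraction, rel=0.25)


class TestCumulativeReleased:
    def test_constant_rate_hand_integral(self):
        t = np.array([0.0, 1.0, 2.0])
        s = ExcessSeries("soil_pore_co2", "m1", t, np.full(3, 0.02), "rate")
        assert cumulative_released(s, 0.0, 2.0) == pytest.approx(0.96)

    def test_empty_window_is_an_error(self):
        t = np.array([0.0, 1.0, 2.0])
        s = ExcessSeries("soil_pore_co2", "m1", t, np.full(3, 0.02), "rate")
        with pytest.raises(ValueError):
            cumulative_released(s, 5.0, 6.0)

    def test_mass_balance_against_simulator(self):
        """On a dense gas schedule the integral over the chase window
        matches the simulator's cumulative respired label within 2%
        (trapezoid error only)."""
        from dataclasses import replace
        from pinetrace.isotope import build_excess_series
        from pinetrace.efflux import efflux_series
        from pinetrace.simulate import default_scenario, simulate_campaign
        dense = (-1.0, *np.arange(0.25, 47.01, 0.25))
        scenario = replace(default_scenario(seed=13).zero_noise(),
                           gas_times=dense)
        table, truth = simulate_campaign(scenario)
        env = table.environment[table.environment["mesocosm_id"] == "C1"]
        s = build_excess_series(
            table, "soil_pore_co2", "C1",
            flux_model=lambda t: efflux_series(scenario.efflux_params, env, t))
        got = cumulative_released(s, 0.0, 47.0)
        assert got == pytest.approx(truth.cum_respired("control", 47.0),
                                    rel=0.02)


class TestPeakTime:
    def test_monotone_series_peaks_at_last_point(self):
        s = ExcessSeries("x", "m1", TIMES, TIMES ** 2)
        assert peak_time(s) == TIMES[-1]

    def test_ties_resolve_to_earliest(self):
        s = ExcessSeries("x", "m1", TIMES, np.array([0, 5, 5, 3, 2, 1.0]))
        assert peak_time(s) == 1.0

    def test_simulated_efflux_and_fungal_peaks(self, default_campaign):
        """Control efflux excess peaks at day 5; fungal PLFA at day 2."""
        from pinetrace import pipeline
        scenario, table, _ = default_campaign
        assert pipeline.efflux_peak_day(
            table, "control", scenario.efflux_params) == pytest.approx(5.0)
        assert pipeline.fungal_peak_day(table, "control") == pytest.approx(2.0)
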