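"""Rate estimation: smoothing, mass-balance derivatives, point extraction."""

import numpy as np
import pytest

import couptake as cu
from couptake.rates import (
    CultivationTimeSeries,
    extract_rate_points,
    frame_to_rate_points,
    rate_points_to_frame,
    smooth_savgol,
    specific_uptake_rate,
)


class TestSavgol:
    def test_constant_series_unchanged(self):
        v = np.full(25, 3.7)
        assert np.allclose(smooth_savgol(v, 11, 3), v)

    def test_quadratic_reproduced_exactly(self):
        t = np.linspace(0, 5, 31)
        v = 2.0 + 0.5 * t - 0.3 * t**2
        assert np.allclose(smooth_savgol(v, 11, 3), v, atol=1e-10)

    def test_noise_reduction_on_sine(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0, 4 * np.pi, 200)
        clean = np.sin(t)
        noisy = clean + rng.normal(0, 0.1, t.size)
        smoothed = smooth_savgol(noisy, 11, 3)
        assert np.sqrt(np.mean((smoothed - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2))

    def test_length_preserved_and_guards(self):
        v = np.arange(20.0)
        assert smooth_savgol(v, 5, 2).size == v.size
        with pytest.raises(ValueError):
            smooth_savgol(v, 4, 2)  # even window
        with pytest.raises(ValueError):
            smooth_savgol(v, 21, 2)  # window > length
        with pytest.raises(ValueError):
            smooth_savgol(v, 3, 3)  # polyorder >= window

    def test_derivative_of_constant_is_zero(self):
        d = cu.savgol_derivative(np.full(15, 2.0), 11, 3, dt=0.1)
        assert np.allclose(d, 0.0, atol=1e-12)


class TestSpecificUptakeRate:
    def test_unconsumed_substrate_gives_zero(self):
        t = np.arange(0, 3, 0.1)
        q = specific_uptake_rate(np.full(t.size, 5.0), np.full(t.size, 10.0), np.zeros(t.size), t)
        assert np.allclose(q, 0.0, atol=1e-12)

    def test_linear_consumption_closed_form(self):
        t = np.arange(0, 3, 0.1)
        mass = 100.0 - 2.0 * t  # consumed at 2 g/h
        q = specific_uptake_rate(mass, np.full(t.size, 10.0), np.zeros(t.size), t)
        assert np.allclose(q, 0.2, atol=1e-9)

    def test_fed_and_consumed_balance(self):
        t = np.arange(0, 3, 0.1)
        mass = np.full(t.size, 4.0)  # steady pool: uptake equals feed
        feed = np.full(t.size, 3.0)
        q = specific_uptake_rate(mass, np.full(t.size, 10.0), feed, t)
        assert np.allclose(q, 0.3, atol=1e-9)

    def test_zero_biomass_rejected(self):
        t = np.arange(0, 1, 0.1)
        with pytest.raises(ValueError):
            specific_uptake_rate(np.ones(t.size), np.zeros(t.size), np.zeros(t.size), t)


class TestExtraction:
    def test_round_trip_recovers_setpoint(self, static_run, default_truth):
        """Noise-free static cultivation yields rates at the commanded setpoint."""
        pts = [p for p in extract_rate_points(static_run.series) if p.timestamp >= 2.5]
        assert len(pts) >= 10
        qg = np.array([p.qs_glu for p in pts])
        ql = np.array([p.qs_lac_max_meas for p in pts])
        model_val = cu.eval_qs_lac_max(default_truth.params, 0.25)
        assert np.all(np.abs(qg - 0.25) / 0.25 < 0.02)
        assert abs(ql.mean() - model_val) / model_val < 0.02

    def test_ramp_round_trip_against_truth(self, ramp_run, default_truth):
        """Estimated rates track the simulator's realized rates within 2%."""
        pts = extract_rate_points(ramp_run.series)
        truth = ramp_run.truth.set_index("time_h")
        # away from the phase breakpoint at t=2 h (derivative window spans it)
        checked = 0
        for p in pts:
            if not 3.0 <= p.timestamp <= 4.6:
                continue
            row = truth.loc[p.timestamp]
            assert abs(p.qs_glu - row.qs_glu_true) / row.qs_glu_true < 0.02
            assert abs(p.qs_lac_max_meas - row.qs_lac_true) / row.qs_lac_true < 0.02
            checked += 1
        assert checked >= 5

    def test_low_lactose_samples_excluded(self, static_run):
        series = static_run.series
        starved = CultivationTimeSeries(
            time=series.time,
            dcw_conc=series.dcw_conc,
            volume=series.volume,
            glucose_conc=series.glucose_conc,
            lactose_conc=np.full(len(series), 2.0),  # below the 5 g/L floor
            feed_rate=series.feed_rate,
            phase=series.phase,
        )
        with pytest.warns(UserWarning):
            pts = extract_rate_points(starved)
        assert pts == []

    def test_no_induced_phase_rejected(self, static_run):
        series = static_run.series
        uninduced = CultivationTimeSeries(
            time=series.time,
            dcw_conc=series.dcw_conc,
            volume=series.volume,
            glucose_conc=series.glucose_conc,
            lactose_conc=series.lactose_conc,
            feed_rate=series.feed_rate,
            phase=np.array(["fedbatch"] * len(series), dtype=object),
        )
        with pytest.raises(ValueError, match="induced"):
            extract_rate_points(uninduced)

    def test_sigma_floor_and_cv(self, static_run):
        pts = extract_rate_points(static_run.series, sigma_cv=0.10)
        for p in pts:
            assert p.sigma >= 0.002
            assert p.sigma == pytest.approx(max(0.10 * p.qs_lac_max_meas, 0.002))

    def test_mass_consistency(self, static_run):
        """Integrated uptake*biomass matches total lactose consumed within 3%."""
        series = static_run.series
        pts = extract_rate_points(series)
        t = np.array([p.timestamp for p in pts])
        ql = np.array([p.qs_lac_max_meas for p in pts])
        X = np.interp(t, series.time, series.dcw_conc * series.volume)
        consumed_est = np.trapezoid(ql * X, t)
        M_lac = series.lactose_conc * series.volume
        i0, i1 = np.searchsorted(series.time, t[0]), np.searchsorted(series.time, t[-1])
        consumed_true = M_lac[i0] - M_lac[i1]
        assert abs(consumed_est - consumed_true) / consumed_true < 0.03


def test_rate_point_frame_round_trip():
    pts = [cu.RatePoint(0.1, 0.05, 0.005, 1.0), cu.RatePoint(0.2, 0.08, 0.008, 2.0)]
    assert frame_to_rate_points(rate_points_to_frame(pts)) == pts


def test_rate_point_invariants():
    with pytest.raises(ValueError):
        cu.RatePoint(0.1, 0.05, 0.0, 1.0)
    with pytest.raises(ValueError):
        cu.RatePoint(-0.1, 0.05, 0.01, 1.0)
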