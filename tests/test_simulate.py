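"""Fed-batch simulator: conservation, adaptation, accumulation, noise."""

import numpy as np
import pytest

import couptake as cu
from couptake.protocols import (
    ExperimentProtocol,
    LactosePulse,
    Phase,
    adaptation_ramp_protocol,
    static_induction_protocol,
)
from couptake.simulate import SimTruth, add_measurement_noise, make_rate_points, perturb_rate_points


def glucose_closure(balances: dict) -> float:
    fed = balances["glucose_initial"] + balances["glucose_fed"]
    gap = fed - balances["glucose_consumed"] - balances["glucose_residual"]
    return abs(gap) / max(fed, 1e-9)


def lactose_closure(balances: dict) -> float:
    supplied = balances["lactose_initial"] + balances["lactose_pulsed"]
    gap = supplied - balances["lactose_consumed"] - balances["lactose_residual"]
    return abs(gap) / max(supplied, 1e-9)


class TestConservation:
    @pytest.mark.parametrize("setpoint", [0.0, 0.1, 0.25, 0.5])
    def test_static_protocol_balances(self, setpoint):
        out = cu.simulate(static_induction_protocol(setpoint, duration=4.0), cu.SimTruth())
        assert glucose_closure(out.balances) < 0.005
        assert lactose_closure(out.balances) < 0.005

    def test_ramp_protocol_balances(self, ramp_run):
        assert glucose_closure(ramp_run.balances) < 0.005
        assert lactose_closure(ramp_run.balances) < 0.005

    def test_biomass_never_decreases_volume_increases(self, static_run):
        s = static_run.series
        X = s.dcw_conc * s.volume
        assert np.all(np.diff(X) >= -1e-9)
        assert np.all(np.diff(s.volume) > 0)  # feeding throughout


class TestGlucoseCapacity:
    def test_no_accumulation_below_cap(self, static_run):
        # commanded 0.25 < default batch capacity; residual glucose stays trace
        assert np.all(static_run.series.glucose_conc < 0.05)

    def test_monotone_accumulation_above_cap(self):
        truth = SimTruth(q_glu_cap=0.32)
        protocol = ExperimentProtocol(
            name="cap_crossing",
            phases=(
                Phase("induced", 2.0, 0.25, 0.0, 10.0),
                Phase("induced", 1.5, 0.25, 0.14, 10.0),  # crosses 0.32 at ~0.5 h
            ),
            pulses=(LactosePulse(0.0, 25.0),),
        )
        out = cu.simulate(protocol, truth)
        above = out.truth.qs_glu_cmd.to_numpy() > 0.33
        g = out.series.glucose_conc[above]
        assert g.size > 3
        assert np.all(np.diff(g) > 0)
        assert np.all(out.truth.qs_glu_true.to_numpy()[above] <= 0.32 + 1e-6)

    def test_zero_feed_glucose_non_increasing(self):
        protocol = ExperimentProtocol(
            name="no_feed",
            phases=(Phase("induced", 3.0, 0.0, 0.0, 10.0),),
            pulses=(LactosePulse(0.0, 25.0),),
        )
        out = cu.simulate(protocol, SimTruth(glucose0=1.0))
        assert np.all(np.diff(out.series.glucose_conc) <= 1e-12)


class TestAdaptation:
    def test_fully_adapted_after_two_hours(self, static_run, default_truth):
        tr = static_run.truth
        a2 = tr.loc[np.isclose(tr.time_h, 2.0), "adaptation"].iloc[0]
        assert a2 >= 0.98
        late = tr[tr.time_h >= 2.0]
        model_val = cu.eval_qs_lac_max(default_truth.params, 0.25)
        assert np.all(np.abs(late.qs_lac_true - model_val) / model_val < 0.025)

    def test_hysteresis_between_up_and_down_ramps(self):
        """Adapted cells ramped down outperform unadapted cells ramped up."""
        truth = SimTruth()
        up = ExperimentProtocol(
            name="cold_up",
            phases=(Phase("induced", 2.5, 0.0, 0.2, 10.0),),
            pulses=(LactosePulse(0.0, 25.0),),
        )
        down = ExperimentProtocol(
            name="adapted_down",
            phases=(
                Phase("induced", 2.0, 0.25, 0.0, 10.0),
                Phase("induced", 2.5, 0.25, -0.1, 10.0),
            ),
            pulses=(LactosePulse(0.0, 25.0),),
        )
        out_up = cu.simulate(up, truth)
        out_dn = cu.simulate(down, truth)
        for q in (0.1, 0.2):
            lac_up = np.interp(q, out_up.truth.qs_glu_true, out_up.truth.qs_lac_true)
            tr_dn = out_dn.truth[out_dn.truth.time_h > 2.0].sort_values("qs_glu_true")
            lac_dn = np.interp(q, tr_dn.qs_glu_true, tr_dn.qs_lac_true)
            assert lac_dn > lac_up

    def test_lactose_floor_triggers_repulse(self):
        truth = SimTruth()
        protocol = ExperimentProtocol(
            name="long_low_lactose",
            phases=(Phase("induced", 12.0, 0.25, 0.0, 30.0),),
            pulses=(LactosePulse(0.0, 8.0),),  # small pulse, will be consumed
            lactose_floor=5.0,
            pulse_target=20.0,
        )
        out = cu.simulate(protocol, truth)
        assert np.all(out.series.lactose_conc >= 5.0 - 1e-9)
        assert out.balances["lactose_pulsed"] > 8.0 * truth.V0  # repulsed at least once


class TestNoise:
    def test_deterministic_given_seed(self, static_run):
        a = add_measurement_noise(static_run.series, seed=42)
        b = add_measurement_noise(static_run.series, seed=42)
        assert np.array_equal(a.dcw_conc, b.dcw_conc)
        assert np.array_equal(a.lactose_conc, b.lactose_conc)

    def test_zero_cv_is_identity(self, static_run):
        a = add_measurement_noise(static_run.series, cv_range=(0.0, 0.0), seed=1)
        assert np.allclose(a.glucose_conc, static_run.series.glucose_conc)

    def test_time_and_control_channels_untouched(self, static_run):
        a = add_measurement_noise(static_run.series, seed=3)
        assert np.array_equal(a.time, static_run.series.time)
        assert np.array_equal(a.volume, static_run.series.volume)
        assert np.array_equal(a.feed_rate, static_run.series.feed_rate)

    def test_empirical_cv_matches_request(self):
        t = np.arange(1000) * 0.1
        series = cu.CultivationTimeSeries(
            time=t,
            dcw_conc=np.full(t.size, 20.0),
            volume=np.full(t.size, 10.0),
            glucose_conc=np.full(t.size, 1.0),
            lactose_conc=np.full(t.size, 15.0),
            feed_rate=np.zeros(t.size),
            phase=np.array(["induced"] * t.size, dtype=object),
        )
        noisy = add_measurement_noise(series, cv_range=(0.10, 0.10), seed=0)
        for channel in (noisy.dcw_conc, noisy.lactose_conc):
            cv = channel.std() / channel.mean()
            assert 0.085 <= cv <= 0.115

    def test_rate_level_noise_cv(self):
        pts = make_rate_points(cu.parameter_set("scfv"), [0.2], replicates=2000, seed=0)
        noisy = perturb_rate_points(pts, noise_cv=0.10, seed=0)
        vals = np.array([p.qs_lac_max_meas for p in noisy])
        assert 0.085 <= vals.std() / vals.mean() <= 0.115


class TestBenchmarkSuite:
    def test_shapes_and_recovery(self, default_truth, clean_combined_points):
        suite = cu.generate_benchmark_suite(default_truth, seed=0, noise=False)
        assert set(suite) == {"static", "ramp_up", "combined"}
        assert len(suite["ramp_up"]["points"]) >= 12  # 10-min sampling over the ramp
        res = cu.fit(suite["static"]["points"], seed=0)
        for name in cu.PARAM_NAMES:
            tol = 0.25 if name == "K_A" else 0.05
            est, tru = getattr(res.params, name), getattr(default_truth.params, name)
            assert abs(est - tru) / tru < tol, name
        assert len(clean_combined_points) > 30

    def test_truth_serialization_round_trip(self, default_truth):
        d = default_truth.to_dict()
        assert SimTruth.from_dict(d) == default_truth


def test_sim_truth_invariants():
    with pytest.raises(ValueError):
        SimTruth(tau_up=3.0, tau_down=1.0)
    with pytest.raises(ValueError):
        SimTruth(Y_XS_glu=1.5)
    with pytest.raises(ValueError):
        SimTruth(q_glu_cap=-0.1)
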