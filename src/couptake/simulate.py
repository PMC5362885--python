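"""Fed-batch induction simulator.

Generates the data structure the analysis pipeline assumes: static-setpoint
fed-batches with lactose in excess, q_s,glu ramps with a lactose-adaptation
lag, glucose accumulation once commanded uptake exceeds the cells' capacity,
and multiplicative 7–15% measurement noise on the measured channels.

State variables (absolute masses; concentrations would be biased by the
volume added through feeding):

    X      absolute biomass [g]
    V      broth volume [L]
    M_glu  glucose mass in the broth [g]
    M_lac  lactose mass in the broth [g]
    A      lactose-adaptation state in [0, 1]

The adaptation state follows first-order dynamics towards 1 while lactose is
present (time constant tau_up, ~0.5 h so cells are ~fully adapted after
2 h) and decays back with the slower tau_down when lactose disappears — the
asymmetry reproduces the hysteresis between up-ramps from unadapted cells
and down-ramps after adaptation, and the slow loss of lactose uptake
capacity over time.  Effective lactose uptake is A times the mechanistic
model evaluated at the *realized* glucose uptake rate.  Glucose commanded
above the uptake capacity accumulates in the broth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import bioprocess
from .kinetics import UptakeModelParams, eval_qs_lac_max
from .protocols import ExperimentProtocol, static_induction_protocol, adaptation_ramp_protocol
from .rates import SIGMA_FLOOR, CultivationTimeSeries, RatePoint, extract_rate_points

__all__ = [
    "SimTruth",
    "SimulationOutput",
    "simulate",
    "add_measurement_noise",
    "make_rate_points",
    "generate_benchmark_suite",
]

DEFAULT_PARAMS = UptakeModelParams(0.13, 0.094, 1.02, 1.48, 0.040)


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth physiology and initial state of a simulated cultivation."""

    params: UptakeModelParams = DEFAULT_PARAMS
    tau_up: float = 0.5  # adaptation time constant while lactose present [h]
    tau_down: float = 3.0  # decay of lactose machinery after removal [h]
    q_glu_cap: float | None = None  # glucose uptake capacity [g/g/h]; None = batch max
    qs_glu_max_batch: float = 1.3  # unrestricted glucose uptake [g/g/h]
    Y_XS_glu: float = 0.37  # biomass yield on glucose [g/g]
    Y_XS_lac: float = 0.37  # biomass yield on lactose [g/g]
    X0_conc: float = 25.0  # biomass at induction start [g DCW/L]
    V0: float = 10.0  # initial broth volume [L]
    glucose0: float = 0.05  # initial residual glucose [g/L]
    lactose0: float = 0.0  # initial lactose [g/L]
    glu_relax_h: float = 0.05  # backlog-consumption relaxation time [h]
    Km_lac: float = 0.05  # residual-lactose half-saturation [g/L]
    lactose_presence_threshold: float = 0.5  # [g/L] drives adaptation target

    def __post_init__(self) -> None:
        if not self.tau_up < self.tau_down:
            raise ValueError("tau_up must be smaller than tau_down")
        if self.q_glu_cap is not None and self.q_glu_cap <= 0:
            raise ValueError("q_glu_cap must be positive when set")
        for name in ("Y_XS_glu", "Y_XS_lac"):
            y = getattr(self, name)
            if not 0 < y < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.X0_conc <= 0 or self.V0 <= 0:
            raise ValueError("initial biomass and volume must be positive")

    def to_dict(self) -> dict[str, Any]:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["params"] = self.params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimTruth":
        d = dict(d)
        d["params"] = UptakeModelParams.from_dict(d["params"])
        return cls(**d)


@dataclass(frozen=True)
class SimulationOutput:
    """Noise-free sampled series plus the per-sample ground truth."""

    series: CultivationTimeSeries
    truth: pd.DataFrame  # time_h, qs_glu_cmd, qs_glu_true, qs_lac_true, adaptation
    balances: dict[str, float] = field(default_factory=dict)


def _uptake_capacity(truth: SimTruth, kind: str) -> float:
    if kind == "induced" and truth.q_glu_cap is not None:
        return truth.q_glu_cap
    return truth.qs_glu_max_batch


def _derivatives(
    state: np.ndarray, truth: SimTruth, q_cmd: float, kind: str, controller: str = "true_biomass"
) -> tuple[np.ndarray, float, float]:
    """Right-hand side; also returns the realized specific uptake rates."""
    X, V, M_glu, M_lac, A = state[:5]
    c_glu = max(M_glu, 0.0) / V
    c_lac = max(M_lac, 0.0) / V

    if controller == "soft_sensor":
        # yield-based estimate from the glucose feed balance (state[5])
        X_ctrl = truth.X0_conc * truth.V0 + truth.Y_XS_glu * state[5]
    else:
        X_ctrl = X
    inflow_glu = q_cmd * X_ctrl  # feed law: F*c_F/rho_F = q_cmd * X_est
    cap = _uptake_capacity(truth, kind)
    # below capacity the cells consume the feed as it arrives plus any
    # residual backlog (relaxed over glu_relax_h, which keeps the glucose
    # pool non-stiff); commanded uptake above capacity accumulates glucose
    u_glu = min(cap * X, inflow_glu + max(M_glu, 0.0) / truth.glu_relax_h)
    q_glu_real = u_glu / X

    if kind == "induced":
        q_lac_real = A * eval_qs_lac_max(truth.params, min(q_glu_real, 50.0)) * c_lac / (c_lac + truth.Km_lac)
    else:
        q_lac_real = 0.0
    u_lac = q_lac_real * X

    lactose_present = c_lac > truth.lactose_presence_threshold
    A_target = 1.0 if lactose_present else 0.0
    tau = truth.tau_up if A_target > A else truth.tau_down
    dA = (A_target - A) / tau

    dX = truth.Y_XS_glu * u_glu + truth.Y_XS_lac * u_lac
    dV = inflow_glu / bioprocess.DEFAULT_CF_GLUCOSE  # feed volume flow [L/h]
    dM_glu = inflow_glu - u_glu
    dM_lac = -u_lac
    # cumulative balances: glucose fed, glucose consumed, lactose consumed
    return (
        np.array([dX, dV, dM_glu, dM_lac, dA, inflow_glu, u_glu, u_lac]),
        q_glu_real,
        q_lac_real,
    )


def simulate(
    protocol: ExperimentProtocol,
    truth: SimTruth | None = None,
    dt: float = 0.001,
    seed: int | None = None,
    controller: str = "true_biomass",
) -> SimulationOutput:
    """Integrate a cultivation protocol with fixed-step 4th-order Runge-Kutta.

    The feed controller realizes the commanded q_s,glu on the true biomass
    (ideal specific-rate control); lactose pulses and the floor rule are
    applied between integration steps.  `seed` is accepted for interface
    symmetry — the core simulation is deterministic; noise is added
    separately by `add_measurement_noise`.
    """
    truth = truth or SimTruth()
    min_sampling_h = min(p.sampling_interval_min for p in protocol.phases) / 60.0
    if dt > min_sampling_h / 5:
        raise ValueError("dt must be at most a fifth of the smallest sampling interval")

    X = truth.X0_conc * truth.V0
    V = truth.V0
    state = np.array([X, V, truth.glucose0 * truth.V0, truth.lactose0 * truth.V0, 0.0, 0.0, 0.0, 0.0])
    pulsed_lac = 0.0
    initial_glu = state[2]
    initial_lac = state[3]

    pending_pulses = sorted(protocol.pulses, key=lambda p: p.time)
    pulse_i = 0

    rec_t: list[float] = []
    rec_rows: list[tuple] = []
    truth_rows: list[tuple] = []

    def apply_pulse(target_conc: float) -> None:
        nonlocal pulsed_lac
        add = max(target_conc * state[1] - state[3], 0.0)
        if add > 0:
            state[3] += add
            state[1] += add / bioprocess.DEFAULT_CF_LACTOSE  # pulse volume from lactose feed
            pulsed_lac += add

    def record(t: float, phase_kind: str, q_cmd: float) -> None:
        d, q_glu_real, q_lac_real = _derivatives(state, truth, q_cmd, phase_kind, controller)
        Xc, Vc = state[0], state[1]
        feed_mass_rate = q_cmd * Xc * bioprocess.DEFAULT_RHO_F / bioprocess.DEFAULT_CF_GLUCOSE
        rec_t.append(t)
        rec_rows.append(
            (Xc / Vc, Vc, max(state[2], 0.0) / Vc, max(state[3], 0.0) / Vc, feed_mass_rate, phase_kind)
        )
        truth_rows.append((t, q_cmd, q_glu_real, q_lac_real, state[4]))

    t_abs = 0.0
    for phase in protocol.phases:
        sampling_h = phase.sampling_interval_min / 60.0
        n_sub = max(int(math.ceil(sampling_h / dt)), 5)
        h = sampling_h / n_sub
        n_samples = int(round(phase.duration / sampling_h))
        t_phase = 0.0
        for s in range(n_samples):
            # pulses and the lactose floor are handled between steps
            while pulse_i < len(pending_pulses) and pending_pulses[pulse_i].time <= t_abs + 1e-9:
                apply_pulse(pending_pulses[pulse_i].target_conc)
                pulse_i += 1
            if s == 0:
                record(t_abs, phase.kind, phase.qs_glu_at(t_phase))
            for _ in range(n_sub):
                # floor rule: lactose must stay in excess throughout induction
                if phase.kind == "induced" and state[3] / state[1] < protocol.lactose_floor:
                    if pulsed_lac > 0 or truth.lactose0 > 0:
                        apply_pulse(protocol.pulse_target)
                q_cmd = phase.qs_glu_at(t_phase + h / 2)  # midpoint command over the step
                k1, _, _ = _derivatives(state, truth, q_cmd, phase.kind, controller)
                k2, _, _ = _derivatives(state + h / 2 * k1, truth, q_cmd, phase.kind, controller)
                k3, _, _ = _derivatives(state + h / 2 * k2, truth, q_cmd, phase.kind, controller)
                k4, _, _ = _derivatives(state + h * k3, truth, q_cmd, phase.kind, controller)
                state += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
                if state[3] < 0:
                    warnings.warn("lactose driven below 0; clipped", stacklevel=2)
                    state[3] = 0.0
                if state[2] < 0:
                    state[2] = 0.0
                state[4] = min(max(state[4], 0.0), 1.0)
                t_phase += h
                t_abs += h
            record(t_abs, phase.kind, phase.qs_glu_at(t_phase))

    rows = np.array([r[:5] for r in rec_rows], dtype=float)
    # drop duplicate timestamps at phase joins (keep the later record)
    t_arr = np.asarray(rec_t)
    keep = np.ones(t_arr.size, dtype=bool)
    keep[:-1] = np.diff(t_arr) > 1e-9
    series = CultivationTimeSeries(
        time=t_arr[keep],
        dcw_conc=rows[keep, 0],
        volume=rows[keep, 1],
        glucose_conc=rows[keep, 2],
        lactose_conc=rows[keep, 3],
        feed_rate=rows[keep, 4],
        phase=np.array([rec_rows[i][5] for i in np.where(keep)[0]], dtype=object),
    )
    truth_df = pd.DataFrame(
        np.array([truth_rows[i] for i in np.where(keep)[0]], dtype=float),
        columns=["time_h", "qs_glu_cmd", "qs_glu_true", "qs_lac_true", "adaptation"],
    )
    fed_glu, cons_glu, cons_lac = state[5], state[6], state[7]
    balances = {
        "glucose_fed": float(fed_glu),
        "glucose_consumed": float(cons_glu),
        "glucose_residual": float(max(state[2], 0.0)),
        "glucose_initial": float(initial_glu),
        "lactose_pulsed": float(pulsed_lac),
        "lactose_consumed": float(cons_lac),
        "lactose_residual": float(max(state[3], 0.0)),
        "lactose_initial": float(initial_lac),
    }
    return SimulationOutput(series=series, truth=truth_df, balances=balances)


def add_measurement_noise(
    ts: CultivationTimeSeries,
    cv_range: tuple[float, float] = (0.07, 0.15),
    seed: int = 0,
) -> CultivationTimeSeries:
    """Multiplicative lognormal noise on the measured channels.

    Each measured channel (biomass, glucose, lactose concentration) gets an
    independent coefficient of variation drawn uniformly from `cv_range`;
    time, volume and the feed signal are control/balance quantities and stay
    untouched.  Deterministic given the seed.
    """
    lo, hi = cv_range
    if lo < 0 or hi >= 1 or lo > hi:
        raise ValueError("cv_range must satisfy 0 <= lo <= hi < 1")
    rng = np.random.default_rng(seed)
    out = {}
    for name in ("dcw_conc", "glucose_conc", "lactose_conc"):
        values = getattr(ts, name)
        cv = rng.uniform(lo, hi)
        if cv == 0:
            out[name] = values.copy()
            continue
        sigma = math.sqrt(math.log(1.0 + cv**2))
        factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=values.size)
        out[name] = values * factors
    return CultivationTimeSeries(
        time=ts.time.copy(),
        dcw_conc=out["dcw_conc"],
        volume=ts.volume.copy(),
        glucose_conc=out["glucose_conc"],
        lactose_conc=out["lactose_conc"],
        feed_rate=ts.feed_rate.copy(),
        phase=ts.phase.copy(),
    )


def perturb_rate_points(
    points: list[RatePoint],
    noise_cv: float = 0.10,
    seed: int = 0,
) -> list[RatePoint]:
    """Multiplicative lognormal error on measured lactose uptake rates.

    Emulates the reported 7–15% relative error of the (q_s,glu,
    q_s,lac,max) data points directly at the rate level; each point's sigma
    is reset to ``noise_cv * measured`` (floored).  Deterministic given the
    seed.
    """
    if noise_cv < 0 or noise_cv >= 1:
        raise ValueError("noise_cv must be in [0, 1)")
    if noise_cv == 0:
        return list(points)
    rng = np.random.default_rng(seed)
    s = math.sqrt(math.log(1.0 + noise_cv**2))
    factors = rng.lognormal(-0.5 * s**2, s, size=len(points))
    return [
        RatePoint(
            qs_glu=p.qs_glu,
            qs_lac_max_meas=max(p.qs_lac_max_meas * f, 0.0),
            sigma=max(noise_cv * p.qs_lac_max_meas * f, SIGMA_FLOOR),
            timestamp=p.timestamp,
        )
        for p, f in zip(points, factors)
    ]


def make_rate_points(
    params: UptakeModelParams,
    qs_glu_values,
    noise_cv: float = 0.0,
    sigma_cv: float = 0.10,
    replicates: int = 1,
    seed: int = 0,
) -> list[RatePoint]:
    """Rate points drawn directly from the model (no cultivation layer).

    Handy for parameter-recovery and identifiability studies where the
    measurement layer is not under test.  `noise_cv` is the actual relative
    error applied; `sigma_cv` the per-point sigma assigned for weighting.
    """
    rng = np.random.default_rng(seed)
    q = np.repeat(np.asarray(qs_glu_values, dtype=float), replicates)
    y_true = np.atleast_1d(eval_qs_lac_max(params, q))
    if noise_cv > 0:
        s = math.sqrt(math.log(1.0 + noise_cv**2))
        y = y_true * rng.lognormal(-0.5 * s**2, s, size=y_true.size)
    else:
        y = y_true.copy()
    return [
        RatePoint(float(qi), float(max(yi, 0.0)), max(sigma_cv * float(yi), SIGMA_FLOOR), float(i))
        for i, (qi, yi) in enumerate(zip(q, y))
    ]


# -- benchmark designs --------------------------------------------------------

#: static setpoints as fractions of qs_glu_crit (8 levels over [0, 0.8*crit]);
#: the second level sits at the low-q point the combination design pairs with
#: the ramp (~0.074 g/g/h for the tandem-scFv critical rate)
STATIC_SETPOINT_FRACTIONS = (0.0, 0.0725, 0.125, 0.2, 0.3, 0.45, 0.62, 0.8)


def _collect_points(
    out: SimulationOutput,
    noise: bool,
    sigma_cv: float,
    seed: int,
    t_min: float,
) -> list[RatePoint]:
    # rates are estimated from the clean series; the reported 7-15% error
    # band applies to the rate points themselves, so noise goes on at the
    # rate level (concentration noise would be amplified arbitrarily by the
    # numerical derivative and no longer carry the stated CV)
    pts = extract_rate_points(out.series, sigma_cv=sigma_cv)
    pts = [p for p in pts if p.timestamp >= t_min]
    return perturb_rate_points(pts, noise_cv=sigma_cv, seed=seed) if noise else pts


def generate_benchmark_suite(
    truth: SimTruth | None = None,
    seed: int = 0,
    noise: bool = True,
    sigma_cv: float = 0.10,
) -> dict[str, dict[str, Any]]:
    """Three labelled benchmark datasets mirroring the characterization designs.

    static   : 8 constant-setpoint fed-batches over [0, 0.8*qs_glu_crit]
    ramp_up  : 2 h adaptation at 0.25 g/g/h then a +0.14 g/g/h^2 ramp up
               towards 0.8*qs_glu_crit
    combined : ramp_up plus the two low static experiments (no-glucose and
               ~0.074 g/g/h)

    Rate points are taken after the adaptation transient has settled
    (t >= 2.5 h for statics, ramp portion for the dynamic run).
    """
    truth = truth or SimTruth()
    qc = truth.params.qs_glu_crit
    setpoints = [f * qc for f in STATIC_SETPOINT_FRACTIONS]

    static_points: list[RatePoint] = []
    static_series: list[CultivationTimeSeries] = []
    per_setpoint: dict[float, list[RatePoint]] = {}
    for i, sp in enumerate(setpoints):
        out = simulate(static_induction_protocol(sp, duration=6.0, sampling_min=10.0), truth)
        pts = _collect_points(out, noise, sigma_cv, seed=(seed * 1000 + i) % (2**31 - 1), t_min=2.5)
        per_setpoint[sp] = pts
        static_points.extend(pts)
        static_series.append(out.series)

    # ramp from the adaptation setpoint up towards the critical rate (the
    # same upper extent the static suite covers)
    ramp_hours = max((0.8 * qc - 0.25) / 0.14, 0.5)
    ramp_protocol = adaptation_ramp_protocol(ramp_h=ramp_hours)
    ramp_out = simulate(ramp_protocol, truth)
    ramp_points = _collect_points(
        ramp_out, noise, sigma_cv, seed=(seed * 1000 + 100) % (2**31 - 1), t_min=2.0
    )

    low_sp = setpoints[1]  # ~0.074 g/g/h for the tandem-scFv critical rate
    combined_points = list(ramp_points) + list(per_setpoint[setpoints[0]]) + list(per_setpoint[low_sp])

    return {
        "static": {"points": static_points, "series": static_series, "setpoints": setpoints},
        "ramp_up": {"points": ramp_points, "series": [ramp_out.series], "protocol": ramp_protocol},
        "combined": {"points": combined_points, "series": None, "setpoints": [setpoints[0], low_sp]},
    }
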