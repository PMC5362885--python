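"""Model-based experiment design via local parameter sensitivity.

Each model parameter is disturbed by ±10% and the resulting deviation of the
predicted q_s,lac,max curve is scanned over a fine q_s,glu grid.  The
glucose-uptake setpoints where a parameter's deviation peaks carry the most
information for estimating that parameter; they become the recommended
measurement points.  The module also emits the three-experiment
characterization protocol (batch + lactose pulse; low-setpoint fed-batch;
adaptation followed by a linear q_s,glu ramp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetics import PARAM_NAMES, UptakeModelParams, eval_qs_lac_max
from .protocols import ExperimentProtocol, LactosePulse, Phase

__all__ = [
    "SensitivityMap",
    "sensitivity_map",
    "recommend_points",
    "three_experiment_plan",
    "optimal_replicate_design",
]

#: two default grid steps: recommended points closer than this are merged
DEDUP_RADIUS = 0.02

#: protocol constants of the three-experiment strategy
ADAPT_QS = 0.25  # adaptation setpoint [g/g/h]
ADAPT_HOURS = 2.0
RAMP_RATE = 0.14  # [g/g/h^2]
MAX_INDUCED_HOURS = 5.0
LOW_SETPOINT_RANGE = (0.05, 0.15)  # [g/g/h]


@dataclass(frozen=True)
class SensitivityMap:
    """Per-parameter |Δ q_s,lac,max| deviation curves over a q_s,glu grid."""

    qs_glu_grid: np.ndarray
    deviations: dict[str, np.ndarray]
    argmax: dict[str, float]
    delta: float

    def to_frame(self) -> pd.DataFrame:
        """Long format: (param, qs_glu, deviation)."""
        frames = [
            pd.DataFrame({"param": name, "qs_glu": self.qs_glu_grid, "deviation": dev})
            for name, dev in self.deviations.items()
        ]
        return pd.concat(frames, ignore_index=True)


def sensitivity_map(
    params: UptakeModelParams,
    delta: float = 0.10,
    grid_step: float = 0.01,
    grid: np.ndarray | None = None,
) -> SensitivityMap:
    """±delta disturbance of each parameter; deviation curve and its argmax.

    The grid spans [0, qs_glu_crit]; per grid point the larger of the two
    one-sided deviations is recorded.  Ties in the argmax resolve to the
    lowest q_s,glu.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if grid is None:
        grid = np.arange(0.0, params.qs_glu_crit + grid_step / 2, grid_step)
        grid = np.clip(grid, 0.0, params.qs_glu_crit)
    else:
        grid = np.asarray(grid, dtype=float)
        if np.any(grid < 0) or np.any(grid > params.qs_glu_crit + 1e-12):
            raise ValueError("grid must lie within [0, qs_glu_crit]")
    base = np.atleast_1d(eval_qs_lac_max(params, grid))
    deviations: dict[str, np.ndarray] = {}
    argmax: dict[str, float] = {}
    for name in PARAM_NAMES:
        p0 = getattr(params, name)
        dev = np.zeros_like(base)
        for sign in (+1.0, -1.0):
            perturbed = params.replace(**{name: p0 * (1.0 + sign * delta)})
            dev = np.maximum(dev, np.abs(np.atleast_1d(eval_qs_lac_max(perturbed, grid)) - base))
        deviations[name] = dev
        argmax[name] = float(grid[int(np.argmax(dev))])
    return SensitivityMap(qs_glu_grid=grid, deviations=deviations, argmax=argmax, delta=delta)


def recommend_points(sens: SensitivityMap, k: int) -> list[float]:
    """The k most informative q_s,glu measurement points, ascending.

    Takes the per-parameter deviation argmax locations, drops parameters
    whose deviation is identically ~0, merges locations closer than the
    dedup radius, and returns the k lowest.  (The low-q_s,glu region hosts
    the argmaxes of the affinity and zero-glucose parameters — exactly the
    ones static mid-range data pin down worst — so truncation keeps the low
    end first.)
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    candidates = sorted(
        sens.argmax[name]
        for name in sens.argmax
        if float(np.max(sens.deviations[name])) > 1e-12
    )
    if not candidates:
        warnings.warn("all sensitivity deviations are zero; no points to recommend", stacklevel=2)
        return []
    merged: list[float] = []
    for q in candidates:
        if not merged or q - merged[-1] > DEDUP_RADIUS:
            merged.append(q)
    return merged[:k]


def _relative_jacobian(params: UptakeModelParams, q: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian of the model curve w.r.t. the parameters."""
    p0 = params.to_array()
    J = np.empty((q.size, p0.size))
    for j, name in enumerate(PARAM_NAMES):
        h = max(1e-6, 1e-6 * abs(p0[j]))
        up = params.replace(**{name: p0[j] + h})
        dn = params.replace(**{name: max(p0[j] - h, 0.0)})
        J[:, j] = (
            np.atleast_1d(eval_qs_lac_max(up, q)) - np.atleast_1d(eval_qs_lac_max(dn, q))
        ) / (p0[j] + h - max(p0[j] - h, 0.0))
    return J


def optimal_replicate_design(
    params: UptakeModelParams,
    n_points: int = 24,
    cv: float = 0.10,
    sigma_floor: float = 0.002,
    support_step: float = 0.01,
    upper_fraction: float = 0.95,
) -> dict[float, int]:
    """Allocate measurement replicates over q_s,glu by greedy D-optimality.

    Sharpens the max-deviation heuristic into a quantitative design: the
    expected information of a measurement at q is its weighted sensitivity
    outer product; replicates are added one at a time wherever the
    determinant of the relative-scale Fisher information grows most.  The
    allocation typically concentrates on the very low-q region (affinity and
    zero-glucose parameters), the curve shoulder and the high-q tail — the
    same regions the deviation argmaxes point at.

    Returns a mapping q_s,glu setpoint -> number of replicates summing to
    `n_points`.
    """
    if n_points < 5:
        raise ValueError("need at least as many points as parameters")
    support = np.round(
        np.arange(0.0, upper_fraction * params.qs_glu_crit + 1e-9, support_step), 6
    )
    y = np.atleast_1d(eval_qs_lac_max(params, support))
    sigma = np.maximum(cv * y, sigma_floor)
    Jw = _relative_jacobian(params, support) / sigma[:, None]
    atoms = np.einsum("ij,ik->ijk", Jw, Jw)
    scale = np.outer(params.to_array(), params.to_array())

    def neg_logdet(F: np.ndarray) -> float:
        sign, ld = np.linalg.slogdet(F * scale)
        return -ld if sign > 0 else np.inf

    w = np.zeros(support.size, dtype=int)
    m = support.size - 1
    for frac in (0.0, 0.125, 0.375, 0.625, 0.875):  # nonsingular spread seed
        w[int(round(frac * m))] += 1
    while int(w.sum()) < n_points:
        base = np.tensordot(w, atoms, axes=1)
        scores = np.array([neg_logdet(base + atoms[i]) for i in range(support.size)])
        w[int(np.argmin(scores))] += 1
    return {float(support[i]): int(w[i]) for i in range(support.size) if w[i]}


def three_experiment_plan(params_guess: UptakeModelParams) -> list[ExperimentProtocol]:
    """The three-cultivation characterization strategy as executable protocols.

    1. batch, then a lactose pulse with no glucose feed (pins qs_lac_noglu);
    2. induced fed-batch at a low setpoint around 0.1 g/g/h (the sensitivity
       analysis locates the affinity information there);
    3. 2 h lactose adaptation at 0.25 g/g/h, then a +0.14 g/g/h^2 linear
       ramp, capped so the induced time stays under 5 h.
    """
    sens = sensitivity_map(params_guess)
    low_candidates = [q for q in recommend_points(sens, k=3) if 0.0 < q <= 0.2]
    low = low_candidates[0] if low_candidates else 0.1
    low = float(np.clip(low, *LOW_SETPOINT_RANGE))

    batch_pulse = ExperimentProtocol(
        name="batch_lactose_pulse",
        phases=(
            Phase("batch", 3.0, sampling_interval_min=30.0),
            Phase("induced", 4.0, qs_glu=0.0, sampling_interval_min=30.0),
        ),
        pulses=(LactosePulse(3.0, 25.0),),
    )
    low_static = ExperimentProtocol(
        name="static_low_qs",
        phases=(Phase("induced", 4.5, qs_glu=low, sampling_interval_min=10.0),),
        pulses=(LactosePulse(0.0, 25.0),),
    )
    ramp_hours = min(
        (0.8 * params_guess.qs_glu_crit - ADAPT_QS) / RAMP_RATE,
        MAX_INDUCED_HOURS - ADAPT_HOURS - 0.1,
    )
    ramp_hours = max(ramp_hours, 0.5)
    adapt_ramp = ExperimentProtocol(
        name="adapt_ramp_up",
        phases=(
            Phase("induced", ADAPT_HOURS, qs_glu=ADAPT_QS, sampling_interval_min=10.0),
            Phase("induced", ramp_hours, qs_glu=ADAPT_QS, ramp_rate=RAMP_RATE, sampling_interval_min=10.0),
        ),
        pulses=(LactosePulse(0.0, 25.0),),
    )
    return [batch_pulse, low_static, adapt_ramp]
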