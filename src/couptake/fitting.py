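"""Weighted least-squares fitting of the co-uptake model.

The five model parameters are estimated from (q_s,glu, q_s,lac,max) rate
points by minimizing the sigma-weighted sum of squared residuals

    S = sum_i ((q_s,lac,max,meas,i - q_s,lac,max,model,i) / sigma_i)^2

with the Nelder-Mead simplex, under physiologically meaningful parameter
bounds.  Bounds are enforced by a smooth coordinate transformation (each
parameter is mapped into its interval through a scaled logistic), so the
simplex itself runs unconstrained and never stalls on penalty cliffs.

Two entry styles are provided: plain functions (`fit`, `fixed_param_fit`,
`objective_S`) and a statsmodels-flavoured pair `UptakeKineticsModel` /
`UptakeKineticsResults` whose ``summary()`` prints an estimation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .kinetics import PARAM_NAMES, UptakeModelParams, eval_qs_lac_max, nrmse
from .rates import RatePoint, frame_to_rate_points

__all__ = [
    "ParameterBounds",
    "FitResult",
    "objective_S",
    "fit",
    "fixed_param_fit",
    "UptakeKineticsModel",
    "UptakeKineticsResults",
]

#: default physiological bounds [g/g/h except n], spanning all published
#: parameter sets with margin
DEFAULT_BOUNDS = {
    "qs_lac_max_star": (0.0, 0.5),
    "K_A": (1e-4, 1.0),
    "qs_glu_crit": (0.3, 2.0),
    "n": (0.1, 5.0),
    "qs_lac_noglu": (0.0, 0.2),
}


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter [min, max] boxes for the five model parameters."""

    bounds: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_BOUNDS)
        for k, v in dict(self.bounds).items():
            if k not in PARAM_NAMES:
                raise KeyError(f"unknown parameter {k!r}")
            merged[k] = (float(v[0]), float(v[1]))
        for k, (lo, hi) in merged.items():
            if not lo < hi:
                raise ValueError(f"bounds for {k}: min must be < max")
            if lo < 0:
                raise ValueError(f"bounds for {k}: min must be >= 0")
        object.__setattr__(self, "bounds", merged)

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bounds[name]

    def contains(self, params: UptakeModelParams, atol: float = 1e-9) -> bool:
        return all(
            self.bounds[k][0] - atol <= getattr(params, k) <= self.bounds[k][1] + atol
            for k in PARAM_NAMES
        )

    def midpoint(self) -> UptakeModelParams:
        return UptakeModelParams.from_dict(
            {k: 0.5 * (lo + hi) for k, (lo, hi) in self.bounds.items()}
        )

    def to_arrays(self, names: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[k][0] for k in names])
        hi = np.array([self.bounds[k][1] for k in names])
        return lo, hi


@dataclass(frozen=True)
class FitResult:
    """Outcome of one weighted fit."""

    params: UptakeModelParams
    S: float
    nrmse_pct: float
    n_points: int
    converged: bool
    n_restarts_used: int
    seed: int
    fixed: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "params": self.params.to_dict(),
            "S": self.S,
            "nrmse_pct": self.nrmse_pct,
            "n_points": self.n_points,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "seed": self.seed,
            "fixed": dict(self.fixed),
        }


def _point_arrays(points: Sequence[RatePoint]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if not points:
        raise ValueError("need at least one rate point")
    q = np.array([p.qs_glu for p in points])
    y = np.array([p.qs_lac_max_meas for p in points])
    sig = np.array([p.sigma for p in points])
    if np.any(sig <= 0):
        raise ValueError("all sigmas must be > 0")
    return q, y, sig


def objective_S(params: UptakeModelParams, points: Sequence[RatePoint]) -> float:
    """Weighted sum of squared residuals; 0 iff the model passes through every point."""
    q, y, sig = _point_arrays(points)
    resid = (y - eval_qs_lac_max(params, q)) / sig
    return float(np.sum(resid**2))


# -- bounded Nelder-Mead machinery -------------------------------------------

_LOGIT_CLIP = 1e-9


def _to_internal(p: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    u = np.clip((p - lo) / (hi - lo), _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
    return np.log(u / (1.0 - u))


def _to_external(z: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return lo + (hi - lo) * expit(z)


def _validate_points_for_fit(points: Sequence[RatePoint], n_free: int) -> None:
    if len(points) < max(n_free, 1):
        raise ValueError(
            f"need at least {n_free} rate points to fit {n_free} free parameters; "
            f"got {len(points)}. Collect more samples or pin parameters."
        )
    distinct = np.unique(np.round([p.qs_glu for p in points], 6))
    if n_free >= 2 and distinct.size < 3:
        raise ValueError(
            "rate points must span at least 3 distinct qs_glu values; "
            f"found {distinct.size}. A single setpoint cannot constrain the curve shape."
        )


def _run_fit(
    points: Sequence[RatePoint],
    bounds: ParameterBounds,
    fixed: Mapping[str, float],
    init: UptakeModelParams | None,
    restarts: int,
    seed: int,
    xatol: float = 1e-8,
    fatol: float = 1e-10,
) -> FitResult:
    for name, value in fixed.items():
        if name not in PARAM_NAMES:
            raise KeyError(f"unknown parameter {name!r}")
        lo, hi = bounds[name]
        if not lo <= value <= hi:
            raise ValueError(f"pinned value {name}={value} outside bounds [{lo}, {hi}]")
    free_names = [k for k in PARAM_NAMES if k not in fixed]
    q, y, sig = _point_arrays(points)

    def assemble(free_vec: np.ndarray) -> UptakeModelParams:
        d = dict(fixed)
        d.update(zip(free_names, free_vec))
        return UptakeModelParams.from_dict(d)

    if not free_names:  # everything pinned: just evaluate
        params = assemble(np.empty(0))
        S = objective_S(params, points)
        model_vals = np.atleast_1d(eval_qs_lac_max(params, q))
        return FitResult(params, S, nrmse(model_vals, y), len(points), True, 0, seed, dict(fixed))

    _validate_points_for_fit(points, len(free_names))
    lo, hi = bounds.to_arrays(free_names)

    def neg_obj(z: np.ndarray) -> float:
        p = _to_external(z, lo, hi)
        try:
            params = assemble(p)
        except ValueError:
            return np.inf
        resid = (y - np.atleast_1d(eval_qs_lac_max(params, q))) / sig
        return float(np.sum(resid**2))

    init_params = init if init is not None else bounds.midpoint()
    z0 = _to_internal(np.array([getattr(init_params, k) for k in free_names]), lo, hi)

    rng = np.random.default_rng(seed)
    starts = [z0] + [z0 + rng.normal(0.0, 1.2, size=z0.size) for _ in range(max(restarts - 1, 0))]

    best_z, best_S, best_ok = None, np.inf, False
    for z_start in starts:
        res = minimize(
            neg_obj,
            z_start,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 4000, "maxfev": 6000},
        )
        # polish: restart the simplex at the solution once
        res = minimize(
            neg_obj,
            res.x,
            method="Nelder-Mead",
            options={"xatol": xatol, "fatol": fatol, "maxiter": 4000, "maxfev": 6000},
        )
        if res.fun < best_S:
            best_z, best_S, best_ok = res.x, float(res.fun), bool(res.success)

    params = assemble(_to_external(best_z, lo, hi))
    model_vals = np.atleast_1d(eval_qs_lac_max(params, q))
    return FitResult(
        params=params,
        S=best_S,
        nrmse_pct=nrmse(model_vals, y),
        n_points=len(points),
        converged=best_ok,
        n_restarts_used=len(starts),
        seed=seed,
        fixed=dict(fixed),
    )


def fit(
    points: Sequence[RatePoint],
    bounds: ParameterBounds | None = None,
    init: UptakeModelParams | None = None,
    restarts: int = 8,
    seed: int = 0,
) -> FitResult:
    """Estimate all five parameters; best of `restarts` seeded Nelder-Mead runs."""
    return _run_fit(points, bounds or ParameterBounds(), {}, init, restarts, seed)


def fixed_param_fit(
    points: Sequence[RatePoint],
    bounds: ParameterBounds | None = None,
    fixed: Mapping[str, float] | None = None,
    seed: int = 0,
    init: UptakeModelParams | None = None,
    restarts: int = 8,
) -> FitResult:
    """Fit with some parameters pinned at given values (identifiability inner solver)."""
    return _run_fit(points, bounds or ParameterBounds(), dict(fixed or {}), init, restarts, seed)


# -- statsmodels-style surface ------------------------------------------------


class UptakeKineticsModel:
    """Co-uptake kinetics model bound to a rate-point dataset.

    Parameters
    ----------
    points : sequence of RatePoint
        Paired (q_s,glu, q_s,lac,max, sigma) observations.
    bounds : ParameterBounds, optional
        Physiological parameter box; defaults span the published fits.
    """

    def __init__(self, points: Sequence[RatePoint], bounds: ParameterBounds | None = None):
        self.points = list(points)
        self.bounds = bounds or ParameterBounds()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, bounds: ParameterBounds | None = None) -> "UptakeKineticsModel":
        """Build from a frame with columns qs_glu, qs_lac_max, sigma, time_h."""
        return cls(frame_to_rate_points(df), bounds)

    def fit(
        self,
        init: UptakeModelParams | None = None,
        restarts: int = 8,
        seed: int = 0,
        fixed: Mapping[str, float] | None = None,
    ) -> "UptakeKineticsResults":
        result = _run_fit(self.points, self.bounds, dict(fixed or {}), init, restarts, seed)
        return UptakeKineticsResults(self, result)

    def profile(self, param_name: str, **kwargs):
        """Practical-identifiability profile of one parameter (see `couptake.identifiability`)."""
        from .identifiability import profile

        return profile(self.points, param_name, bounds=self.bounds, **kwargs)

    def profile_all(self, **kwargs):
        from .identifiability import profile_all

        return profile_all(self.points, bounds=self.bounds, **kwargs)


class UptakeKineticsResults:
    """Estimation results: parameters, objective, fit quality, diagnostics."""

    def __init__(self, model: UptakeKineticsModel, result: FitResult):
        self.model = model
        self.result = result

    @property
    def params(self) -> UptakeModelParams:
        return self.result.params

    @property
    def S(self) -> float:
        return self.result.S

    @property
    def nrmse_pct(self) -> float:
        return self.result.nrmse_pct

    def predict(self, qs_glu) -> np.ndarray | float:
        return eval_qs_lac_max(self.params, qs_glu)

    def identifiability(self, **kwargs):
        """Profile all parameters and classify each (uses this fit as warm start)."""
        from .identifiability import classify, profile_all

        trajectories = profile_all(
            self.model.points, bounds=self.model.bounds, best_fit=self.result, **kwargs
        )
        return {name: classify(traj) for name, traj in trajectories.items()}

    def summary(self) -> str:
        r = self.result
        lines = [
            "Glucose/lactose co-uptake kinetics — weighted NLS (Nelder-Mead)",
            "=" * 64,
            f"No. rate points: {r.n_points:>5}    restarts: {r.n_restarts_used}   seed: {r.seed}",
            f"Objective S:    {r.S:>12.6g}    NRMSE: {r.nrmse_pct:.2f} %",
            f"Converged:      {str(r.converged):>5}",
            "-" * 64,
            f"{'parameter':<18}{'estimate':>12}  {'unit':<8}{'bounds':>18}",
            "-" * 64,
        ]
        units = {"qs_lac_max_star": "g/g/h", "K_A": "g/g/h", "qs_glu_crit": "g/g/h", "n": "-", "qs_lac_noglu": "g/g/h"}
        for name in PARAM_NAMES:
            lo, hi = self.model.bounds[name]
            tag = " (fixed)" if name in r.fixed else ""
            lines.append(
                f"{name:<18}{getattr(r.params, name):>12.4g}  {units[name]:<8}"
                f"{f'[{lo:g}, {hi:g}]':>18}{tag}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<UptakeKineticsResults S={self.S:.4g} nrmse={self.nrmse_pct:.2f}%>"
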