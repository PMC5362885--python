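"""Practical identifiability by objective-function profiling.

For each parameter a physiological range [p_min, p_max] is scanned on a
grid; at every grid value the parameter is pinned and the weighted objective
S is re-minimized over the remaining parameters, giving a trajectory S_p.
A parameter is practically identifiable when S_p has a genuine interior
minimum — i.e. it rises on both sides of the argmin by at least a relative
threshold (default 5%).  A flat trajectory means the data do not constrain
the parameter; an argmin on the range edge means the estimate runs into the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import FitResult, ParameterBounds, fixed_param_fit
from .kinetics import PARAM_NAMES
from .rates import RatePoint

__all__ = ["ProfileTrajectory", "profile", "profile_all", "classify"]

#: parameters profiled on a log-spaced grid (they span orders of magnitude)
LOG_SPACED = {"K_A"}

DEFAULT_RISE_THRESHOLD = 0.05


@dataclass(frozen=True)
class ProfileTrajectory:
    """Re-minimized objective S_p over a grid of pinned parameter values."""

    param_name: str
    grid: np.ndarray
    S_p: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        s = np.asarray(self.S_p, dtype=float)
        if g.size != s.size or g.size == 0:
            raise ValueError("grid and S_p must be non-empty and equal length")
        if np.any(s < 0):
            raise ValueError("objective values must be >= 0")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "S_p", s)

    @property
    def argmin_index(self) -> int:
        return int(np.argmin(self.S_p))

    @property
    def argmin_value(self) -> float:
        return float(self.grid[self.argmin_index])


def _make_grid(p_min: float, p_max: float, n_grid: int, log_spacing: bool) -> np.ndarray:
    if log_spacing:
        if p_min <= 0:
            raise ValueError("log-spaced grid requires p_min > 0")
        return np.geomspace(p_min, p_max, n_grid)
    return np.linspace(p_min, p_max, n_grid)


def profile(
    points: Sequence[RatePoint],
    param_name: str,
    p_min: float | None = None,
    p_max: float | None = None,
    n_grid: int = 21,
    bounds: ParameterBounds | None = None,
    seed: int = 0,
    log_spacing: bool | None = None,
    restarts: int = 4,
    best_fit: FitResult | None = None,
) -> ProfileTrajectory:
    """Profile one parameter over [p_min, p_max] (defaults: its bounds).

    The pinned re-fits are warm-started left-to-right from the neighbouring
    grid point's solution, which keeps the trajectory smooth with few
    restarts.
    """
    if param_name not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param_name!r}; known: {PARAM_NAMES}")
    bounds = bounds or ParameterBounds()
    blo, bhi = bounds[param_name]
    p_min = blo if p_min is None else p_min
    p_max = bhi if p_max is None else p_max
    if not (blo <= p_min < p_max <= bhi):
        raise ValueError("[p_min, p_max] must lie inside the parameter bounds")
    if n_grid < 5:
        raise ValueError("n_grid must be >= 5 for a meaningful trajectory")
    if log_spacing is None:
        log_spacing = param_name in LOG_SPACED
    # a log grid cannot start at 0; nudge onto the smallest representable bound
    if log_spacing and p_min <= 0:
        p_min = max(p_min, 1e-4)
    grid = _make_grid(p_min, p_max, n_grid, log_spacing)

    S_p = np.empty(n_grid)
    init = best_fit.params if best_fit is not None else None
    for i, value in enumerate(grid):
        res = fixed_param_fit(
            points,
            bounds=bounds,
            fixed={param_name: float(value)},
            seed=seed + i,
            init=init,
            restarts=restarts if i == 0 else max(restarts // 2, 1),
        )
        S_p[i] = res.S
        init = res.params  # warm start for the next grid point
    return ProfileTrajectory(param_name=param_name, grid=grid, S_p=S_p)


def profile_all(
    points: Sequence[RatePoint],
    bounds: ParameterBounds | None = None,
    n_grid: int = 21,
    seed: int = 0,
    restarts: int = 4,
    best_fit: FitResult | None = None,
) -> dict[str, ProfileTrajectory]:
    """Profile every model parameter; returns name -> trajectory."""
    bounds = bounds or ParameterBounds()
    return {
        name: profile(
            points,
            name,
            n_grid=n_grid,
            bounds=bounds,
            seed=seed,
            restarts=restarts,
            best_fit=best_fit,
        )
        for name in PARAM_NAMES
    }


def classify(trajectory: ProfileTrajectory, rise_threshold: float = DEFAULT_RISE_THRESHOLD) -> str:
    """Verdict for a profile: 'identifiable' | 'not_identifiable' | 'boundary'.

    identifiable: interior argmin with S_p rising by >= rise_threshold
    (relative to the minimum) towards both ends; boundary: argmin on a grid
    edge; flat trajectories (max relative rise below threshold) are not
    identifiable regardless of where the argmin lands.
    """
    if trajectory.grid.size < 2:
        raise ValueError("cannot classify a degenerate (single-point) trajectory")
    S = trajectory.S_p
    S_min = float(S.min())
    denom = max(S_min, 1e-12)
    i = trajectory.argmin_index
    overall_rise = (float(S.max()) - S_min) / denom
    if overall_rise < rise_threshold:
        return "not_identifiable"
    if i == 0 or i == S.size - 1:
        return "boundary"
    left_rise = (float(S[0]) - S_min) / denom
    right_rise = (float(S[-1]) - S_min) / denom
    if left_rise >= rise_threshold and right_rise >= rise_threshold:
        return "identifiable"
    return "not_identifiable"
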