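"""Mechanistic glucose/lactose co-uptake kinetics.

The central object is the steady-state relationship between the specific
glucose uptake rate ``q_s,glu`` (g glucose / g dry biomass / h) and the maximum
specific lactose uptake rate ``q_s,lac,max`` that fully lactose-adapted
*E. coli* BL21(DE3) cells can sustain at that glucose uptake level:

.. math::

    q_{s,lac,max}(q) =
        \\left( q^{*}_{s,lac,max} \\frac{q}{q + K_A} + q_{s,lac,noglu} \\right)
        \\left( 1 - \\frac{q}{q_{s,glu,crit}} \\right)^{n}
        \\qquad 0 \\le q \\le q_{s,glu,crit}

and 0 above the critical glucose uptake rate.  The saturating first factor
captures the energy requirement of active lactose transport (little glucose
uptake means little ATP for the permease), the power-law second factor
captures carbon catabolite repression: lactose uptake ceases once glucose
uptake exceeds ``q_s,glu,crit``.

Parameters
----------
qs_lac_max_star : maximum specific lactose uptake rate [g/g/h]
K_A             : affinity constant of the energy-supply term [g/g/h]
qs_glu_crit     : critical glucose uptake rate above which lactose uptake
                  stops [g/g/h]
n               : dimensionless repression exponent (> 0)
qs_lac_noglu    : lactose uptake rate at q_s,glu = 0 [g/g/h]
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "UptakeModelParams",
    "RateCurve",
    "PARAM_NAMES",
    "eval_qs_lac_max",
    "eval_curve",
    "nrmse",
    "load_parameter_sets",
    "parameter_set",
]

PARAM_NAMES = ("qs_lac_max_star", "K_A", "qs_glu_crit", "n", "qs_lac_noglu")


@dataclass(frozen=True)
class UptakeModelParams:
    """Parameter set of the co-uptake model (all rates in g/g/h)."""

    qs_lac_max_star: float
    K_A: float
    qs_glu_crit: float
    n: float
    qs_lac_noglu: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        if self.qs_glu_crit <= 0:
            raise ValueError("qs_glu_crit must be > 0")
        if self.n <= 0:
            raise ValueError("exponent n must be > 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "UptakeModelParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (5,):
            raise ValueError("expected 5 parameter values")
        return cls(*values)

    def to_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "UptakeModelParams":
        missing = [k for k in PARAM_NAMES if k not in mapping]
        if missing:
            raise KeyError(f"parameter set is missing keys: {missing}")
        return cls(**{k: float(mapping[k]) for k in PARAM_NAMES})

    def replace(self, **changes: float) -> "UptakeModelParams":
        d = self.to_dict()
        d.update(changes)
        return UptakeModelParams.from_dict(d)


@dataclass(frozen=True)
class RateCurve:
    """A materialized q_s,glu -> q_s,lac,max curve on an increasing grid."""

    qs_glu_grid: np.ndarray
    qs_lac_max_values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.qs_glu_grid, dtype=float)
        vals = np.asarray(self.qs_lac_max_values, dtype=float)
        if grid.size == 0:
            raise ValueError("empty grid")
        if grid.size != vals.size:
            raise ValueError("grid and values must have equal length")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(vals < 0):
            raise ValueError("curve values must be >= 0")
        object.__setattr__(self, "qs_glu_grid", grid)
        object.__setattr__(self, "qs_lac_max_values", vals)


def eval_qs_lac_max(params: UptakeModelParams, qs_glu) -> float | np.ndarray:
    """Evaluate q_s,lac,max at one or many glucose uptake rates.

    Above ``qs_glu_crit`` the rate is 0 (lactose uptake fully repressed); the
    degenerate limit q = K_A = 0 is defined so that the value at q = 0 is
    exactly ``qs_lac_noglu``.
    """
    q = np.asarray(qs_glu, dtype=float)
    if np.any(q < 0) or np.any(~np.isfinite(q)):
        raise ValueError("qs_glu must be finite and >= 0")
    scalar = q.ndim == 0
    q = np.atleast_1d(q)

    denom = q + params.K_A
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(denom > 0, q / np.where(denom > 0, denom, 1.0), 0.0)
    base = 1.0 - q / params.qs_glu_crit
    repress = np.where(base > 0, np.power(np.clip(base, 0.0, None), params.n), 0.0)
    out = (params.qs_lac_max_star * frac + params.qs_lac_noglu) * repress
    out = np.clip(out, 0.0, None)
    return float(out[0]) if scalar else out


def eval_curve(params: UptakeModelParams, grid: Iterable[float]) -> RateCurve:
    """Element-wise model evaluation on a sorted, non-negative grid."""
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    values = np.atleast_1d(eval_qs_lac_max(params, grid))
    return RateCurve(qs_glu_grid=grid, qs_lac_max_values=values)


def nrmse(model_values: Sequence[float], observed: Sequence[float]) -> float:
    """Root-mean-square error normalized by the observation mean, in percent.

    Scale-free: multiplying both vectors by a common positive factor leaves
    the value unchanged.  Raises if the observation mean is zero.
    """
    m = np.asarray(model_values, dtype=float)
    o = np.asarray(observed, dtype=float)
    if m.size == 0 or m.shape != o.shape:
        raise ValueError("model and observed vectors must be non-empty and equal length")
    denom = float(np.mean(o))
    if denom == 0:
        raise ValueError("observed mean is zero; NRMSE undefined")
    return 100.0 * float(np.sqrt(np.mean((m - o) ** 2))) / denom


def load_parameter_sets() -> dict[str, dict[str, UptakeModelParams]]:
    """Load the bundled published parameter sets.

    Returns a two-level mapping: ``strains`` (per-product static fits for
    GFP, HRP, scFv, tandem scFv) and ``datasets`` (the tandem-scFv fits to
    static data, dynamic ramps and their combinations).
    """
    text = resources.files("couptake.data").joinpath("parameter_sets.json").read_text()
    raw = json.loads(text)
    return {
        group: {name: UptakeModelParams.from_dict(entry["params"]) for name, entry in members.items()}
        for group, members in raw.items()
    }


def parameter_set(name: str) -> UptakeModelParams:
    """Look up a bundled parameter set by name across both groups."""
    sets = load_parameter_sets()
    for group in sets.values():
        if name in group:
            return group[name]
    known = sorted(n for g in sets.values() for n in g)
    raise KeyError(f"unknown parameter set {name!r}; known: {known}")
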