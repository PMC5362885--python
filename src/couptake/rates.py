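"""Specific uptake-rate estimation from cultivation time series.

Sampled fed-batch trajectories (biomass, volume, sugar concentrations, feed
rate) are turned into specific uptake rates by Savitzky-Golay smoothing:
concentrations are first converted to absolute masses (feeding dilutes the
broth, so concentration derivatives alone would bias the rates), the mass
derivative is taken analytically from the local Savitzky-Golay polynomial,
and the specific rate follows from the balance

    q_s(t) = (substrate fed rate - d(substrate mass)/dt) / biomass mass .

During lactose-excess induction the measured specific lactose uptake rate is
the *maximum* rate the cells can sustain at the concurrent glucose uptake
level, which is what the co-uptake model predicts; samples where lactose has
fallen out of excess (below the 5 g/L floor) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "CultivationTimeSeries",
    "RatePoint",
    "smooth_savgol",
    "savgol_derivative",
    "specific_uptake_rate",
    "extract_rate_points",
    "rate_points_to_frame",
    "frame_to_rate_points",
]

TS_COLUMNS = (
    "time_h",
    "dcw_g_per_l",
    "volume_l",
    "glucose_g_per_l",
    "lactose_g_per_l",
    "feed_g_per_h",
    "phase",
)

#: absolute floor on the per-point standard deviation [g/g/h]; keeps the
#: weighted objective finite when measured rates approach zero
SIGMA_FLOOR = 0.002


@dataclass(frozen=True)
class CultivationTimeSeries:
    """Sampled fed-batch trajectory.

    time [h] strictly increasing; dcw_conc [g DCW/L]; volume [L];
    glucose_conc / lactose_conc [g/L]; feed_rate [g feed/h]; phase label per
    sample (batch | fedbatch | induced).
    """

    time: np.ndarray
    dcw_conc: np.ndarray
    volume: np.ndarray
    glucose_conc: np.ndarray
    lactose_conc: np.ndarray
    feed_rate: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        n = None
        for name in ("time", "dcw_conc", "volume", "glucose_conc", "lactose_conc", "feed_rate"):
            a = np.asarray(getattr(self, name), dtype=float)
            arrays[name] = a
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError("all columns must have equal length")
        ph = np.asarray(self.phase, dtype=object)
        if ph.size != n:
            raise ValueError("all columns must have equal length")
        if n == 0:
            raise ValueError("empty time series")
        if n > 1 and not np.all(np.diff(arrays["time"]) > 0):
            raise ValueError("time must be strictly increasing")
        for name in ("dcw_conc", "volume", "glucose_conc", "lactose_conc", "feed_rate"):
            if np.any(arrays[name] < -1e-12):
                raise ValueError(f"{name} must be non-negative")
            arrays[name] = np.clip(arrays[name], 0.0, None)
        for name, a in arrays.items():
            object.__setattr__(self, name, a)
        object.__setattr__(self, "phase", ph)

    def __len__(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.time,
                "dcw_g_per_l": self.dcw_conc,
                "volume_l": self.volume,
                "glucose_g_per_l": self.glucose_conc,
                "lactose_g_per_l": self.lactose_conc,
                "feed_g_per_h": self.feed_rate,
                "phase": self.phase,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CultivationTimeSeries":
        missing = [c for c in TS_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"time-series frame is missing column(s): {missing}")
        return cls(
            time=df["time_h"].to_numpy(float),
            dcw_conc=df["dcw_g_per_l"].to_numpy(float),
            volume=df["volume_l"].to_numpy(float),
            glucose_conc=df["glucose_g_per_l"].to_numpy(float),
            lactose_conc=df["lactose_g_per_l"].to_numpy(float),
            feed_rate=df["feed_g_per_h"].to_numpy(float),
            phase=df["phase"].to_numpy(object),
        )


@dataclass(frozen=True)
class RatePoint:
    """One paired (q_s,glu, measured q_s,lac,max) observation with its sigma."""

    qs_glu: float
    qs_lac_max_meas: float
    sigma: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.qs_glu < 0 or self.qs_lac_max_meas < 0:
            raise ValueError("rates must be >= 0")


def _check_savgol_args(n: int, window: int, polyorder: int) -> None:
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= polyorder:
        raise ValueError("window must be greater than polyorder")
    if window > n:
        raise ValueError(f"window ({window}) exceeds series length ({n})")


def smooth_savgol(values, window: int, polyorder: int) -> np.ndarray:
    """Savitzky-Golay smoothing; reproduces polynomials of degree <= polyorder."""
    v = np.asarray(values, dtype=float)
    _check_savgol_args(v.size, window, polyorder)
    return savgol_filter(v, window_length=window, polyorder=polyorder, mode="interp")


def savgol_derivative(values, window: int, polyorder: int, dt: float) -> np.ndarray:
    """First derivative from the local Savitzky-Golay polynomial (uniform dt)."""
    v = np.asarray(values, dtype=float)
    _check_savgol_args(v.size, window, polyorder)
    if dt <= 0:
        raise ValueError("dt must be positive")
    return savgol_filter(v, window_length=window, polyorder=polyorder, deriv=1, delta=dt, mode="interp")


def _uniform_dt(time: np.ndarray, rtol: float = 1e-3) -> float:
    dts = np.diff(time)
    dt = float(np.median(dts))
    if np.any(np.abs(dts - dt) > rtol * dt):
        raise ValueError("time series must be uniformly sampled for derivative estimation")
    return dt


def specific_uptake_rate(
    substrate_mass,
    biomass_mass,
    substrate_fed_rate,
    time,
    window: int | None = None,
    polyorder: int = 3,
) -> np.ndarray:
    """Specific uptake rate series [g/g/h] from mass balance with SG derivative.

    ``q_s(t) = (fed(t) - dM/dt) / X(t)``; negative estimates (smoothing
    wiggle on a substrate that is not consumed) are clipped to 0.
    """
    M = np.asarray(substrate_mass, dtype=float)
    X = np.asarray(biomass_mass, dtype=float)
    F = np.asarray(substrate_fed_rate, dtype=float)
    t = np.asarray(time, dtype=float)
    if not (M.size == X.size == F.size == t.size):
        raise ValueError("all series must have equal length")
    if np.any(X <= 0):
        raise ValueError("biomass must be positive everywhere")
    dt = _uniform_dt(t)
    if window is None:
        window = 11 if dt <= 0.25 else 5
        window = min(window, M.size if M.size % 2 == 1 else M.size - 1)
    dMdt = savgol_derivative(M, window, min(polyorder, window - 1), dt)
    q = (F - dMdt) / X
    return np.clip(q, 0.0, None)


def _pulse_mask(lactose_conc: np.ndarray, window: int, jump_threshold: float = 4.0) -> np.ndarray:
    """True for samples whose derivative window is contaminated by a pulse.

    The filter's local polynomial spans a full window, and near the series
    edges the edge-interpolation polynomial spans the terminal window, so a
    jump invalidates every sample within one window length of it.
    """
    n = lactose_conc.size
    mask = np.zeros(n, dtype=bool)
    jumps = np.where(np.diff(lactose_conc) > jump_threshold)[0]
    for j in jumps:
        lo = max(0, j - window + 1)
        hi = min(n, j + 1 + window)
        mask[lo:hi] = True
        if j >= n - window:  # jump inside the terminal edge-fit window
            mask[n - window:] = True
        if j < window:  # jump inside the leading edge-fit window
            mask[:window] = True
    return mask


def extract_rate_points(
    ts: CultivationTimeSeries,
    sigma_cv: float = 0.10,
    *,
    lactose_floor: float = 5.0,
    feed_substrate_conc: float = 250.0,
    feed_density: float = 1100.0,
    window: int | None = None,
    polyorder: int = 3,
) -> list[RatePoint]:
    """Pair per-sample glucose and lactose uptake rates from the induced phase.

    Samples where lactose is out of excess (< `lactose_floor` g/L) or too
    close to a lactose pulse for the derivative window are excluded.  The
    per-point sigma is ``max(sigma_cv * rate, 0.002 g/g/h)``.
    """
    induced = np.asarray([p == "induced" for p in ts.phase], dtype=bool)
    if not induced.any():
        raise ValueError("no induced-phase samples in time series")
    idx = np.where(induced)[0]
    # use the longest contiguous induced block
    breaks = np.where(np.diff(idx) > 1)[0]
    blocks = np.split(idx, breaks + 1)
    block = max(blocks, key=len)
    t = ts.time[block]
    if t.size < 5:
        raise ValueError("induced phase too short for rate estimation")
    dt = _uniform_dt(t)
    if window is None:
        window = 11 if dt <= 0.25 else 5
        if window > t.size:
            window = t.size if t.size % 2 == 1 else t.size - 1
    V = ts.volume[block]
    X = ts.dcw_conc[block] * V
    M_glu = ts.glucose_conc[block] * V
    M_lac = ts.lactose_conc[block] * V
    glu_inflow = ts.feed_rate[block] * feed_substrate_conc / feed_density

    qs_glu = specific_uptake_rate(M_glu, X, glu_inflow, t, window=window, polyorder=polyorder)
    qs_lac = specific_uptake_rate(M_lac, X, np.zeros_like(t), t, window=window, polyorder=polyorder)

    near_pulse = _pulse_mask(ts.lactose_conc[block], window=window)
    in_excess = ts.lactose_conc[block] > lactose_floor
    keep = in_excess & ~near_pulse

    points = [
        RatePoint(
            qs_glu=float(qs_glu[i]),
            qs_lac_max_meas=float(qs_lac[i]),
            sigma=max(sigma_cv * float(qs_lac[i]), SIGMA_FLOOR),
            timestamp=float(t[i]),
        )
        for i in np.where(keep)[0]
    ]
    if not points:
        warnings.warn(
            "no usable rate points: lactose never in excess "
            f"(> {lactose_floor} g/L) away from pulses",
            stacklevel=2,
        )
    return points


def rate_points_to_frame(points: list[RatePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "qs_glu": [p.qs_glu for p in points],
            "qs_lac_max": [p.qs_lac_max_meas for p in points],
            "sigma": [p.sigma for p in points],
            "time_h": [p.timestamp for p in points],
        }
    )


def frame_to_rate_points(df: pd.DataFrame) -> list[RatePoint]:
    missing = [c for c in ("qs_glu", "qs_lac_max", "sigma", "time_h") if c not in df.columns]
    if missing:
        raise ValueError(f"rate-point frame is missing column(s): {missing}")
    return [
        RatePoint(float(r.qs_glu), float(r.qs_lac_max), float(r.sigma), float(r.time_h))
        for r in df.itertuples()
    ]
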