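"""CSV/JSON readers and writers for the package's domain records.

Schemas
-------
Cultivation time series CSV: time_h, dcw_g_per_l, volume_l, glucose_g_per_l,
lactose_g_per_l, feed_g_per_h, phase.  Rate-point CSV: qs_glu, qs_lac_max,
sigma, time_h.  Parameter sets, protocols, fit results and simulator truth
are JSON.  All round-trips are lossless up to float formatting; rates are
serialized at 3 decimals (g/g/h) where tables are written for people.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from .fitting import FitResult, ParameterBounds
from .kinetics import UptakeModelParams
from .protocols import ExperimentProtocol
from .rates import (
    TS_COLUMNS,
    CultivationTimeSeries,
    RatePoint,
    frame_to_rate_points,
    rate_points_to_frame,
)
from .simulate import SimTruth

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "read_rate_points_csv",
    "write_rate_points_csv",
    "read_params_json",
    "write_params_json",
    "read_bounds_json",
    "read_protocol_json",
    "write_protocol_json",
    "read_truth_json",
    "write_truth_json",
    "write_fit_result_json",
    "read_fit_result_json",
]


def read_timeseries_csv(path: str | Path) -> CultivationTimeSeries:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    return CultivationTimeSeries.from_frame(df)


def write_timeseries_csv(ts: CultivationTimeSeries, path: str | Path) -> None:
    ts.to_frame().to_csv(path, index=False)


def read_rate_points_csv(path: str | Path) -> list[RatePoint]:
    df = pd.read_csv(path, float_precision="round_trip")
    try:
        return frame_to_rate_points(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_rate_points_csv(points: list[RatePoint], path: str | Path) -> None:
    rate_points_to_frame(points).to_csv(path, index=False)


def read_params_json(path: str | Path) -> UptakeModelParams:
    data = json.loads(Path(path).read_text())
    if "params" in data:  # allow the bundled fixture entry shape
        data = data["params"]
    return UptakeModelParams.from_dict(data)


def write_params_json(params: UptakeModelParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_bounds_json(path: str | Path) -> ParameterBounds:
    data = json.loads(Path(path).read_text())
    return ParameterBounds({k: tuple(v) for k, v in data.items()})


def read_protocol_json(path: str | Path) -> ExperimentProtocol:
    return ExperimentProtocol.from_dict(json.loads(Path(path).read_text()))


def write_protocol_json(protocol: ExperimentProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=2) + "\n")


def read_truth_json(path: str | Path) -> SimTruth:
    return SimTruth.from_dict(json.loads(Path(path).read_text()))


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2) + "\n")


def write_fit_result_json(result: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n")


def read_fit_result_json(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())
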