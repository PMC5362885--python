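"""Experiment protocols: feed schedules, lactose pulses, sampling plans.

A protocol is an ordered list of phases.  Each phase commands either a
constant specific glucose uptake setpoint or a linear ramp, and carries its
own sampling interval.  Lactose is managed by explicit pulses (raise the
broth to a target concentration) plus an automatic floor rule: whenever the
lactose concentration falls below the floor during an induced phase it is
pulsed back up, so induction is never substrate-limited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

__all__ = ["Phase", "LactosePulse", "ExperimentProtocol"]

PHASE_KINDS = ("batch", "fedbatch", "induced")


@dataclass(frozen=True)
class Phase:
    """One feeding phase.

    duration [h]; qs_glu [g/g/h] setpoint at phase start; ramp_rate [g/g/h^2]
    (0 for a static phase); sampling_interval_min [min].
    """

    kind: str
    duration: float
    qs_glu: float = 0.0
    ramp_rate: float = 0.0
    sampling_interval_min: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in PHASE_KINDS:
            raise ValueError(f"phase kind must be one of {PHASE_KINDS}, got {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("phase duration must be > 0")
        if self.qs_glu < 0:
            raise ValueError("qs_glu setpoint must be >= 0")
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling interval must be > 0")

    def qs_glu_at(self, t_in_phase: float) -> float:
        return max(0.0, self.qs_glu + self.ramp_rate * t_in_phase)


@dataclass(frozen=True)
class LactosePulse:
    """Instantaneous lactose addition at `time` [h] to `target_conc` [g/L]."""

    time: float
    target_conc: float

    def __post_init__(self) -> None:
        if self.time < 0 or self.target_conc < 0:
            raise ValueError("pulse time and target concentration must be >= 0")


@dataclass(frozen=True)
class ExperimentProtocol:
    """Full cultivation schedule driving the simulator (and emitted by design)."""

    name: str
    phases: tuple[Phase, ...]
    pulses: tuple[LactosePulse, ...] = ()
    lactose_floor: float = 5.0
    pulse_target: float = 25.0

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        if self.lactose_floor < 0:
            raise ValueError("lactose floor must be >= 0")
        object.__setattr__(self, "phases", tuple(self.phases))
        object.__setattr__(self, "pulses", tuple(self.pulses))

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)

    @property
    def induced_duration(self) -> float:
        return sum(p.duration for p in self.phases if p.kind == "induced")

    def phase_at(self, t: float) -> tuple[Phase, float]:
        """Phase active at absolute time t [h] and the time elapsed within it."""
        t0 = 0.0
        for p in self.phases:
            if t < t0 + p.duration or p is self.phases[-1]:
                return p, min(max(t - t0, 0.0), p.duration)
            t0 += p.duration
        raise AssertionError("unreachable")

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "phases": [
                {
                    "kind": p.kind,
                    "duration": p.duration,
                    "qs_glu": p.qs_glu,
                    "ramp_rate": p.ramp_rate,
                    "sampling_interval_min": p.sampling_interval_min,
                }
                for p in self.phases
            ],
            "pulses": [{"time": pl.time, "target_conc": pl.target_conc} for pl in self.pulses],
            "lactose_floor": self.lactose_floor,
            "pulse_target": self.pulse_target,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExperimentProtocol":
        return cls(
            name=d.get("name", "protocol"),
            phases=tuple(Phase(**p) for p in d["phases"]),
            pulses=tuple(LactosePulse(**p) for p in d.get("pulses", ())),
            lactose_floor=float(d.get("lactose_floor", 5.0)),
            pulse_target=float(d.get("pulse_target", 25.0)),
        )


def static_induction_protocol(
    qs_glu: float,
    duration: float = 6.0,
    sampling_min: float = 10.0,
    name: str | None = None,
) -> ExperimentProtocol:
    """Induced fed-batch at a constant q_s,glu setpoint with an initial lactose pulse."""
    return ExperimentProtocol(
        name=name or f"static_qs_{qs_glu:g}",
        phases=(Phase("induced", duration, qs_glu, 0.0, sampling_min),),
        pulses=(LactosePulse(0.0, 25.0),),
    )


def adaptation_ramp_protocol(
    adapt_qs: float = 0.25,
    adapt_h: float = 2.0,
    ramp_rate: float = 0.14,
    ramp_h: float = 2.9,
    sampling_min: float = 10.0,
    name: str = "adapt_ramp_up",
) -> ExperimentProtocol:
    """2 h lactose adaptation at an intermediate setpoint, then a linear q_s,glu ramp."""
    phases = (
        Phase("induced", adapt_h, adapt_qs, 0.0, sampling_min),
        Phase("induced", ramp_h, adapt_qs, ramp_rate, sampling_min),
    )
    return ExperimentProtocol(name=name, phases=phases, pulses=(LactosePulse(0.0, 25.0),))
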