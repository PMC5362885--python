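"""Feed-rate control law and yield-based biomass soft sensor.

Fed-batch cultivations control the specific glucose uptake rate ``q_s,glu``
open-loop: the feed pump rate is computed from the current (estimated)
absolute biomass and the feed composition,

    F = q_s,glu * X * rho_F / c_F      [g feed / h]

and the absolute biomass itself is estimated on-line from the cumulative
feed balance assuming a constant biomass yield on glucose,

    X = c_X0 * V_R + Y_XS * m_F * c_F / rho_F   [g]

where ``m_F * c_F / rho_F`` is the glucose mass delivered so far.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = ["FeedContext", "feed_rate", "biomass_soft_sensor", "broth_volume"]

#: defaults for a 250 g/L glucose / 200 g/L lactose feed system
DEFAULT_RHO_F = 1100.0  # feed density [g/L]
DEFAULT_RHO_R = 1020.0  # broth density [g/L]
DEFAULT_CF_GLUCOSE = 250.0  # glucose feed concentration [g/L]
DEFAULT_CF_LACTOSE = 200.0  # lactose feed concentration [g/L]
DEFAULT_Y_XS = 0.37  # biomass yield on glucose [g DCW / g]


@dataclass(frozen=True)
class FeedContext:
    """Feed/broth properties and the running feed balance.

    rho_F, c_F in g/L; c_X0 initial biomass concentration [g/L]; V_R initial
    reactor volume [L]; Y_XS biomass yield [g/g]; m_F cumulative feed mass
    delivered [g] (the balance signal).
    """

    rho_F: float = DEFAULT_RHO_F
    c_F: float = DEFAULT_CF_GLUCOSE
    c_X0: float = 8.5
    V_R: float = 10.0
    rho_R: float = DEFAULT_RHO_R
    Y_XS: float = DEFAULT_Y_XS
    m_F: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho_F", "c_F", "c_X0", "V_R", "rho_R", "Y_XS"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m_F < 0:
            raise ValueError("m_F must be >= 0")
        if self.c_F > self.rho_F:
            raise ValueError("feed substrate concentration cannot exceed feed density")

    def with_feed_mass(self, m_F: float) -> "FeedContext":
        return replace(self, m_F=m_F)


def feed_rate(qs_glu: float, X: float, ctx: FeedContext) -> float:
    """Feed mass flow [g/h] realizing a glucose uptake setpoint.

    Linear in both the setpoint and the absolute biomass ``X`` [g].
    """
    if qs_glu < 0:
        raise ValueError("qs_glu must be >= 0")
    if X < 0:
        raise ValueError("biomass must be >= 0")
    return qs_glu * X * ctx.rho_F / ctx.c_F


def biomass_soft_sensor(ctx: FeedContext) -> float:
    """Absolute biomass estimate [g] from the cumulative feed balance.

    Initial biomass plus yield times glucose mass fed; exact while all growth
    is glucose-limited (non-induced fed-batch), a lower bound once cells also
    grow on lactose.
    """
    return ctx.c_X0 * ctx.V_R + ctx.Y_XS * ctx.m_F * ctx.c_F / ctx.rho_F


def broth_volume(ctx: FeedContext, initial_broth_mass: float | None = None) -> float:
    """Broth volume [L] from the feed balance, assuming constant broth density."""
    m0 = ctx.rho_R * ctx.V_R if initial_broth_mass is None else initial_broth_mass
    return (m0 + ctx.m_F) / ctx.rho_R
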