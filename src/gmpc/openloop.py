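"""Open-loop feed predictor: analytic bolus demands from fixed growth rates
and the genome-scale rate map, with no feedback.

With exponential biomass x(t) = x₀·e^{μt} and a constant specific exchange
rate r, the substrate demand over an interval Δt on a per-litre basis is the
closed form of the demand integral

    F = Mw · ∫₀^{Δt} r · x(t) dt = Mw · r · x₀ · (e^{μΔt} − 1) / μ   [mg·L⁻¹]

(with the continuous limit Mw·r·x₀·Δt at μ = 0).  The planner walks the
phase schedule, extrapolates biomass with the fixed light/dark growth rates,
and emits one bolus per phase start: nitrate every phase, glucose only at
dark-phase starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as C
from .plant import BolusEvent, PhaseSchedule
from .ratemap import GrowthMode, RateMap, default_ratemap

__all__ = ["OpenLoopConfig", "bolus_demand", "plan_feeds"]


@dataclass(frozen=True)
class OpenLoopConfig:
    """Fixed-rate open-loop settings.

    Growth rates default to the reference values used with the calibrated
    rate map; the feed interval is the dark-phase length (light phases are
    fed over their own duration).
    """

    mu_light: float = C.MU_LIGHT     # h⁻¹
    mu_dark: float = C.MU_DARK       # h⁻¹
    feed_interval: float = 8.0       # h
    ratemap: RateMap = field(default_factory=default_ratemap)
    x0: float = 0.1                  # gDW·L⁻¹
    g0: float = 0.0                  # mg·L⁻¹
    n0: float = 0.0                  # mg·L⁻¹
    mw_glucose: float = C.MW_GLUCOSE
    mw_nitrate: float = C.MW_NITRATE

    def __post_init__(self):
        if self.mu_light <= 0 or self.mu_dark <= 0:
            raise ValueError("growth rates must be > 0")
        if self.feed_interval <= 0:
            raise ValueError("feed interval must be > 0")


def bolus_demand(x0: float, mu: float, r: float, dt: float, mw: float) -> float:
    """Substrate demand (mg·L⁻¹) over ``dt`` hours for exponential biomass.

    Exact closed form of Mw·∫ r·x₀e^{μt} dt; ``expm1`` keeps the μ → 0 limit
    (F = Mw·r·x₀·dt) continuous to machine precision.
    """
    if min(x0, mu, r, dt, mw) < 0:
        raise ValueError("bolus_demand arguments must be >= 0")
    if mu == 0.0:
        return mw * r * x0 * dt
    return mw * r * x0 * math.expm1(mu * dt) / mu


def plan_feeds(
    config: OpenLoopConfig, schedule: PhaseSchedule, horizon: float
) -> list[BolusEvent]:
    """Plan all boluses over ``horizon`` hours, consulting no measurements.

    One event per phase start: dark starts get glucose + nitrate for the dark
    interval, light starts get nitrate only for the light interval.  Biomass
    is extrapolated forward with the fixed per-phase growth rates from
    ``config.x0``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    events: list[BolusEvent] = []
    x = config.x0
    for start, end, mode in schedule.segments(0.0, horizon):
        dt = end - start
        if mode is GrowthMode.DARK:
            mu = config.mu_dark
            r_g, r_n = config.ratemap.rates(mode, mu)
            events.append(BolusEvent(
                time=start,
                f_g=bolus_demand(x, mu, r_g, dt, config.mw_glucose),
                f_n=bolus_demand(x, mu, r_n, dt, config.mw_nitrate),
            ))
        else:
            mu = config.mu_light
            _, r_n = config.ratemap.rates(mode, mu)
            events.append(BolusEvent(
                time=start,
                f_g=0.0,
                f_n=bolus_demand(x, mu, r_n, dt, config.mw_nitrate),
            ))
        x *= math.exp(mu * dt)
    return events
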