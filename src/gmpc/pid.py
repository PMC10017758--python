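"""Discrete PID controller baseline for the feed-control comparisons.

Standard positional form with rectangle-rule integral and a
backward-difference derivative taken on the measurement (not the error), so
setpoint steps do not kick the derivative term:

    u_k = K_p·e_k + K_i·Σ e_i·Δt − K_d·(y_k − y_{k−1})/Δt

The output is a feed amount in mg·L⁻¹ for the interval, floored at 0 (a pump
cannot withdraw substrate).  Anti-windup is conditional integration: while
the output is saturated at 0 and the error keeps pushing it negative, the
integral does not accumulate; it is also hard-clamped to ±integral_limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from . import constants as C

__all__ = ["PidGains", "PidState", "pid_step"]


@dataclass(frozen=True)
class PidGains:
    """PID gains; units make u come out in mg·L⁻¹ per control interval."""

    kp: float = C.PID_KP            # dimensionless
    ki: float = C.PID_KI            # h⁻¹
    kd: float = C.PID_KD            # h
    integral_limit: float = float("inf")   # clamp on |∫e dt|, mg·L⁻¹·h

    def __post_init__(self):
        for name in ("kp", "ki", "kd", "integral_limit"):
            v = getattr(self, name)
            if v != v:  # NaN
                raise ValueError(f"PidGains.{name} must be finite")


@dataclass(frozen=True)
class PidState:
    """Accumulators carried between control steps; fresh state = reset."""

    integral: float = 0.0
    prev_error: float | None = None
    prev_measured: float | None = None
    last_t: float | None = None


def pid_step(
    state: PidState,
    gains: PidGains,
    setpoint: float,
    measured: float,
    dt: float,
) -> tuple[float, PidState]:
    """One discrete PID update; returns (feed amount mg·L⁻¹, new state)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    e = setpoint - measured
    integral = state.integral + e * dt
    if state.prev_measured is None:
        deriv = 0.0
    else:
        deriv = -(measured - state.prev_measured) / dt
    u = gains.kp * e + gains.ki * integral + gains.kd * deriv
    if u < 0.0:
        # Saturated low: only let the integral move if it helps desaturate.
        if e < 0.0:
            integral = state.integral
        u = 0.0
    lim = gains.integral_limit
    integral = max(-lim, min(lim, integral))
    return u, replace(
        state, integral=integral, prev_error=e, prev_measured=measured,
        last_t=(0.0 if state.last_t is None else state.last_t) + dt,
    )
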