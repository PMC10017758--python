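"""Bioreactor plant simulator: light/dark cycles, bolus feeds, shading,
mixotrophic dark-phase growth, and noisy sampling.

The plant is the synthetic stand-in for a 2 L algal culture.  State is
biomass x (gDW·L⁻¹), glucose G and nitrate N (mg·L⁻¹), volume V (L) and the
clock t (h).  Dynamics:

LIGHT (autotrophic)::

    dx/dt = μ0·exp(−k·x[mg/L]) · x                (light shading)
    dN/dt = −Mw_N · r_N(μ) · f_N · x              (r_N from the rate map)
    dG/dt = 0                                     (no glucose uptake in light)

DARK (heterotrophic, optionally mixotrophic)::

    μ_H = μ_H,max · f_G · f_N      f_G = G/(K_G+G),  f_N = N/(K_N+N)
    μ_A = μ_A,max · f_N            (CO₂-fixing fraction, light-independent here)
    dx/dt = (a·μ_A + μ_H) · x
    dG/dt = −Mw_G · r_G(μ_H) · x
    dN/dt = −Mw_N · (a·r_NA(μ_A) + r_NH(μ_H)) · x

Monod factors make uptake shut off smoothly at substrate exhaustion so
concentrations never go negative.  Boluses are instantaneous with exact
volume/dilution bookkeeping; the volume only changes at boluses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import constants as C
from .errors import IntegrationError, ScenarioConfigError
from .ratemap import GrowthMode, RateMap, default_ratemap

__all__ = [
    "PlantState",
    "PhaseSchedule",
    "PlantParams",
    "BolusEvent",
    "Trajectory",
    "Measurement",
    "plant_derivative",
    "apply_bolus",
    "integrate",
    "sample_measurement",
]


# ---------------------------------------------------------------------------
# State & configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantState:
    """Bioreactor state at time ``t`` (h)."""

    t: float = 0.0
    x: float = 0.1      # biomass, gDW·L⁻¹
    g: float = 0.0      # glucose, mg·L⁻¹
    n: float = 0.0      # nitrate, mg·L⁻¹
    v: float = 2.0      # volume, L

    def __post_init__(self):
        if self.x < 0 or self.g < 0 or self.n < 0:
            raise ValueError("biomass and substrate concentrations must be >= 0")
        if self.v <= 0:
            raise ValueError("volume must be > 0")


@dataclass(frozen=True)
class PhaseSchedule:
    """Repeating sequence of (mode, duration h) blocks, anchored at t = 0.

    The default is the 16 h light / 8 h dark photoperiod.  A single-block
    schedule (e.g. continuous dark) is allowed; multi-block schedules must
    alternate modes between adjacent blocks.
    """

    blocks: tuple[tuple[GrowthMode, float], ...] = (
        (GrowthMode.LIGHT, 16.0),
        (GrowthMode.DARK, 8.0),
    )

    def __post_init__(self):
        if not self.blocks:
            raise ScenarioConfigError("schedule needs at least one phase block")
        for _, dur in self.blocks:
            if dur <= 0:
                raise ScenarioConfigError("phase durations must be > 0")
        if len(self.blocks) > 1:
            ring = list(self.blocks) + [self.blocks[0]]
            for (m1, _), (m2, _) in zip(ring, ring[1:]):
                if m1 is m2:
                    raise ScenarioConfigError("adjacent phase blocks must alternate modes")

    @classmethod
    def constant(cls, mode: GrowthMode, period: float = 8.0) -> "PhaseSchedule":
        """A schedule that stays in one mode forever (period sets bolus cadence)."""
        return cls(blocks=((mode, period),))

    @property
    def period(self) -> float:
        return sum(dur for _, dur in self.blocks)

    def phase_at(self, t: float) -> GrowthMode:
        """Mode in effect at time ``t`` (phase starts are inclusive)."""
        tau = math.fmod(t, self.period)
        if tau < 0:
            tau += self.period
        for mode, dur in self.blocks:
            if tau < dur - 1e-12:
                return mode
            tau -= dur
        return self.blocks[0][0]

    def segments(self, t0: float, t1: float) -> Iterator[tuple[float, float, GrowthMode]]:
        """Yield (start, end, mode) pieces covering [t0, t1)."""
        t = t0
        while t < t1 - 1e-12:
            tau = math.fmod(t, self.period)
            if tau < 0:
                tau += self.period
            acc = 0.0
            for mode, dur in self.blocks:
                if tau < acc + dur - 1e-9:
                    seg_end = t + (acc + dur - tau)
                    yield t, min(seg_end, t1), mode
                    t = min(seg_end, t1)
                    break
                acc += dur
            else:  # pragma: no cover - defensive
                t = t1

    def boundaries(self, t0: float, t1: float) -> list[float]:
        """Phase-change times strictly inside (t0, t1)."""
        return [s for s, _, _ in self.segments(t0, t1) if t0 < s < t1]

    def phase_starts(self, t0: float, t1: float) -> list[tuple[float, GrowthMode]]:
        """All phase-start instants in [t0, t1), including t0's phase."""
        return [(s, m) for s, _, m in self.segments(t0, t1)]


@dataclass(frozen=True)
class PlantParams:
    """True plant parameters (the controller may assume different ones).

    Defaults reflect the 2 L reference culture: printed shading constants,
    printed feed-stock concentrations and pump flow, heterotrophic growth at
    the dark-cycle reference rate, and modest assay noise.
    """

    ratemap: RateMap = field(default_factory=default_ratemap)
    mu0_light: float = C.SHADING_MU0      # h⁻¹ shading amplitude
    k_shading: float = C.SHADING_K        # per mg·L⁻¹ biomass
    mu_dark_het: float = C.MU_DARK        # h⁻¹ max heterotrophic growth
    mu_dark_auto: float = 0.020           # h⁻¹ mixotrophic autotrophic component
    a_true: float = 0.0                   # dark-phase autotrophic biomass fraction
    k_g: float = 5.0                      # mg·L⁻¹ Monod constant, glucose
    k_n: float = 2.0                      # mg·L⁻¹ Monod constant, nitrate
    sigma_x: float = 5.0                  # mg·L⁻¹ biomass measurement noise s.d.
    sigma_g: float = 2.0                  # mg·L⁻¹ glucose assay noise s.d.
    sigma_n: float = 1.0                  # mg·L⁻¹ nitrate assay noise s.d.
    c_g_stock: float = C.C_G_STOCK        # mg·mL⁻¹
    c_n_stock: float = C.C_N_STOCK        # mg·mL⁻¹
    pump_q: float = C.PUMP_Q              # mL·s⁻¹
    mw_glucose: float = C.MW_GLUCOSE      # mg·mmol⁻¹
    mw_nitrate: float = C.MW_NITRATE      # mg·mmol⁻¹
    dilution: bool = True                 # bolus volume/dilution bookkeeping

    def __post_init__(self):
        if not 0.0 <= self.a_true <= 1.0:
            raise ValueError("a_true must lie in [0, 1]")
        if self.k_g <= 0 or self.k_n <= 0:
            raise ValueError("Monod constants must be > 0")
        for name in ("mu0_light", "k_shading", "mu_dark_het", "mu_dark_auto",
                     "sigma_x", "sigma_g", "sigma_n",
                     "c_g_stock", "c_n_stock", "pump_q",
                     "mw_glucose", "mw_nitrate"):
            if getattr(self, name) < 0:
                raise ValueError(f"PlantParams.{name} must be >= 0")


@dataclass
class BolusEvent:
    """An instantaneous feed: demands in mg per L of culture.

    ``apply_bolus`` fills in the realized pump run-times (s) and the added
    volume (L) once the event hits a plant state.
    """

    time: float
    f_g: float = 0.0
    f_n: float = 0.0
    t_pump_g: float | None = None
    t_pump_n: float | None = None
    added_volume: float | None = None

    def __post_init__(self):
        if self.f_g < 0 or self.f_n < 0:
            raise ValueError("bolus demands must be >= 0")


@dataclass(frozen=True)
class Measurement:
    """A sampled (possibly noisy) observation; biomass in mg·L⁻¹."""

    t: float
    x_m: float   # mg·L⁻¹
    g_m: float   # mg·L⁻¹
    n_m: float   # mg·L⁻¹

    def __post_init__(self):
        if min(self.x_m, self.g_m, self.n_m) < 0:
            raise ValueError("measurements must be >= 0")


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _specific_rates(
    x: float, g: float, n: float, params: PlantParams, mode: GrowthMode
) -> tuple[float, float, float]:
    """Return (μ_total, q_G, q_N): specific growth and uptake rates.

    q are uptake-positive, mmol·gDW⁻¹·h⁻¹.
    """
    g = max(g, 0.0)
    n = max(n, 0.0)
    f_n = n / (params.k_n + n)
    rm = params.ratemap
    if mode is GrowthMode.LIGHT:
        # Growth follows the shading law; nitrate uptake is Monod-limited so
        # it shuts off at exhaustion (biomass N quota is implicit).
        mu = params.mu0_light * math.exp(-params.k_shading * x * 1000.0)
        return mu, 0.0, rm.r_n_light(mu) * f_n
    f_g = g / (params.k_g + g)
    mu_h = params.mu_dark_het * f_g * f_n
    mu_a = params.mu_dark_auto * f_n
    mu = params.a_true * mu_a + mu_h
    q_g = rm.r_g_dark(mu_h)
    q_n = params.a_true * rm.r_n_light(mu_a) + rm.r_n_dark(mu_h)
    return mu, q_g, q_n


def plant_derivative(
    state: PlantState, params: PlantParams, mode: GrowthMode
) -> tuple[float, float, float, float]:
    """Time derivatives (dx/dt, dG/dt, dN/dt, dV/dt) at ``state``.

    Volume is constant between boluses, so dV/dt = 0.
    """
    mu, q_g, q_n = _specific_rates(state.x, state.g, state.n, params, mode)
    dx = mu * state.x
    dg = -params.mw_glucose * q_g * state.x
    dn = -params.mw_nitrate * q_n * state.x
    return dx, dg, dn, 0.0


def apply_bolus(state: PlantState, event: BolusEvent, params: PlantParams) -> PlantState:
    """Apply an instantaneous bolus with exact mixing and dilution.

    Added substrate mass is F·V (mg); added volume is F·V/C (converted to L);
    pump run-time is F·V/(C·Q) seconds.  With ``params.dilution`` False the
    added volume is ignored (concentrations simply increase by F).
    """
    v = state.v
    mass_g = event.f_g * v                      # mg
    mass_n = event.f_n * v                      # mg
    dv_g = mass_g / params.c_g_stock / 1000.0 if event.f_g else 0.0   # L
    dv_n = mass_n / params.c_n_stock / 1000.0 if event.f_n else 0.0   # L
    event.t_pump_g = mass_g / (params.c_g_stock * params.pump_q)      # s
    event.t_pump_n = mass_n / (params.c_n_stock * params.pump_q)      # s
    dv = (dv_g + dv_n) if params.dilution else 0.0
    event.added_volume = dv
    v_new = v + dv
    return replace(
        state,
        x=state.x * v / v_new,
        g=(state.g * v + mass_g) / v_new,
        n=(state.n * v + mass_n) / v_new,
        v=v_new,
    )


# ---------------------------------------------------------------------------
# Trajectory & integration
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time series of plant states plus the boluses that were applied.

    ``frame`` columns: t, phase, x (gDW/L), G, N (mg/L), V (L), and the
    cumulative consumed substrate masses cons_G, cons_N (mg, whole reactor).
    """

    frame: pd.DataFrame
    events: list[BolusEvent] = field(default_factory=list)

    @property
    def t0(self) -> float:
        return float(self.frame["t"].iloc[0])

    @property
    def t_end(self) -> float:
        return float(self.frame["t"].iloc[-1])

    def state_at(self, t: float) -> PlantState:
        """Linearly interpolated state at time ``t`` within the span."""
        tcol = self.frame["t"].to_numpy()
        if t < tcol[0] - 1e-9 or t > tcol[-1] + 1e-9:
            raise ValueError(f"t={t} outside trajectory span [{tcol[0]}, {tcol[-1]}]")
        vals = {
            c: float(np.interp(t, tcol, self.frame[c].to_numpy()))
            for c in ("x", "G", "N", "V")
        }
        return PlantState(t=t, x=vals["x"], g=max(vals["G"], 0.0),
                          n=max(vals["N"], 0.0), v=vals["V"])

    def final_state(self) -> PlantState:
        row = self.frame.iloc[-1]
        return PlantState(t=float(row["t"]), x=float(row["x"]), g=max(float(row["G"]), 0.0),
                          n=max(float(row["N"]), 0.0), v=float(row["V"]))

    def consumed(self, t: float | None = None) -> tuple[float, float]:
        """Cumulative (glucose, nitrate) mass consumed by ``t`` (mg, whole reactor)."""
        if t is None:
            row = self.frame.iloc[-1]
            return float(row["cons_G"]), float(row["cons_N"])
        tcol = self.frame["t"].to_numpy()
        return (
            float(np.interp(t, tcol, self.frame["cons_G"].to_numpy())),
            float(np.interp(t, tcol, self.frame["cons_N"].to_numpy())),
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @staticmethod
    def concatenate(parts: Sequence["Trajectory"]) -> "Trajectory":
        # Boundary rows are duplicated between parts; keep the later part's
        # copy, which reflects the state after any bolus applied there.
        frames = [p.frame.iloc[:-1] for p in parts[:-1]] + [parts[-1].frame]
        events: list[BolusEvent] = []
        for p in parts:
            events.extend(p.events)
        return Trajectory(frame=pd.concat(frames, ignore_index=True), events=events)


def _rhs(params: PlantParams, mode: GrowthMode, v: float):
    def f(_t, y):
        x, g, n = y[0], y[1], y[2]
        mu, q_g, q_n = _specific_rates(x, g, n, params, mode)
        dg = -params.mw_glucose * q_g * x
        dn = -params.mw_nitrate * q_n * x
        # y[3], y[4]: cumulative consumed mass (mg, whole reactor)
        return [mu * x, dg, dn, -dg * v, -dn * v]

    return f


def integrate(
    state: PlantState,
    schedule: PhaseSchedule,
    events: Sequence[BolusEvent],
    horizon: float,
    params: PlantParams,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    sample_dt: float = 0.25,
) -> Trajectory:
    """Integrate the plant over ``horizon`` hours from ``state``.

    Integration restarts at every phase boundary and bolus (the dynamics are
    only piecewise smooth).  Events must be sorted by time; events at the
    start instant are applied before integrating.  Sampling is every
    ``sample_dt`` hours plus all breakpoints.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    t0, t1 = state.t, state.t + horizon
    times = sorted({e.time for e in events if t0 <= e.time <= t1})
    if any(e1.time > e2.time for e1, e2 in zip(events, list(events)[1:])):
        raise ValueError("events must be sorted by time")
    breaks = sorted({t0, t1, *times, *schedule.boundaries(t0, t1)})
    by_time: dict[float, list[BolusEvent]] = {}
    for e in events:
        if t0 <= e.time <= t1:
            by_time.setdefault(e.time, []).append(e)

    rows: list[dict] = []
    applied: list[BolusEvent] = []
    cons_g = cons_n = 0.0
    cur = state

    def record(t, y, v, mode):
        rows.append({
            "t": t, "phase": mode.value, "x": max(y[0], 0.0),
            "G": max(y[1], 0.0), "N": max(y[2], 0.0), "V": v,
            "cons_G": y[3], "cons_N": y[4],
        })

    for left, right in zip(breaks, breaks[1:]):
        for e in by_time.get(left, []):
            cur = apply_bolus(cur, e, params)
            applied.append(e)
        mode = schedule.phase_at(left)
        y0 = [cur.x, cur.g, cur.n, cons_g, cons_n]
        if not rows:
            record(left, y0, cur.v, mode)
        else:  # refresh the breakpoint row post-bolus
            record_row = rows[-1]
            record_row.update(x=cur.x, G=cur.g, N=cur.n, V=cur.v, phase=mode.value)
        n_samples = max(int(math.ceil((right - left) / sample_dt)), 1)
        t_eval = np.linspace(left, right, n_samples + 1)
        sol = solve_ivp(
            _rhs(params, mode, cur.v), (left, right), y0,
            method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval, max_step=np.inf,
        )
        if not sol.success:
            raise IntegrationError(
                f"integration failed in [{left:g}, {right:g}] h: {sol.message}"
            )
        for t, y in zip(sol.t[1:], sol.y.T[1:]):
            record(t, y, cur.v, mode)
        yf = sol.y.T[-1]
        cons_g, cons_n = float(yf[3]), float(yf[4])
        cur = PlantState(t=right, x=max(yf[0], 0.0), g=max(yf[1], 0.0),
                         n=max(yf[2], 0.0), v=cur.v)

    # trailing events exactly at the horizon
    for e in by_time.get(t1, []):
        cur = apply_bolus(cur, e, params)
        applied.append(e)
        rows[-1].update(x=cur.x, G=cur.g, N=cur.n, V=cur.v)

    frame = pd.DataFrame(rows)
    return Trajectory(frame=frame, events=applied)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def sample_measurement(
    traj: Trajectory,
    t: float,
    rng: np.random.Generator | int | None,
    params: PlantParams,
) -> Measurement:
    """Noisy observation of the trajectory at time ``t``.

    Truth is linearly interpolated; additive Gaussian noise with the
    parameterized standard deviations is applied and the result clipped at
    zero.  ``rng`` may be a Generator (shared stream) or an int seed
    (identical seed ⇒ identical measurement); None means noiseless.
    """
    st = traj.state_at(t)  # raises if t outside span
    x_mg = st.x * 1000.0
    if rng is None:
        return Measurement(t=t, x_m=x_mg, g_m=st.g, n_m=st.n)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Measurement(
        t=t,
        x_m=max(x_mg + rng.normal(0.0, params.sigma_x) if params.sigma_x else x_mg, 0.0),
        g_m=max(st.g + rng.normal(0.0, params.sigma_g) if params.sigma_g else st.g, 0.0),
        n_m=max(st.n + rng.normal(0.0, params.sigma_n) if params.sigma_n else st.n, 0.0),
    )
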