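"""Reproducible scenario runner tying plant, controllers and rate map together.

A :class:`Scenario` names a plant configuration, a phase schedule, a
controller and (optionally) setpoint profiles; :func:`run_scenario` executes
it deterministically given its seed and returns the trajectory, the
control log (what the controller measured and fed at each instant) and
summary :class:`ControlMetrics`.

Controllers:

``fed-batch``
    Refeed a fixed glucose bolus whenever the sampled level falls to the
    exhaustion threshold — the conventional baseline.
``open-loop``
    Feeds precomputed by the open-loop predictor; measurements are never
    consulted.
``closed-loop``
    Cycle-wise GMPC: dark-cycle mixed-metabolism fit + light-cycle shading
    predictor, feeding at phase starts.
``pid``
    Two independent hourly PID loops (glucose, nitrate).
``gmpc-setpoint``
    Hourly model-predictive setpoint law (consumption forecast + error
    correction).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import constants as C
from .closedloop import (
    ControllerState,
    DarkFit,
    ShadingLaw,
    calc_demand,
    estimate_mu_from_consumption,
    fit_dark_cycle,
    predict_dark_feed,
    predict_light_feed,
    setpoint_feed,
)
from .errors import ScenarioConfigError
from .openloop import OpenLoopConfig, plan_feeds
from .pid import PidGains, PidState, pid_step
from .plant import (
    BolusEvent,
    Measurement,
    PhaseSchedule,
    PlantParams,
    PlantState,
    Trajectory,
    integrate,
)
from .ratemap import GrowthMode

__all__ = [
    "SetpointProfile",
    "Scenario",
    "ControlMetrics",
    "run_scenario",
    "compute_metrics",
    "scenario_from_yaml",
    "write_outputs",
    "pid_comparison_scenario",
    "fed_batch_scenario",
    "open_loop_scenario",
    "closed_loop_scenario",
    "shipped_scenarios",
]

CONTROLLERS = ("fed-batch", "open-loop", "closed-loop", "pid", "gmpc-setpoint")


@dataclass(frozen=True)
class SetpointProfile:
    """Piecewise-constant setpoint: ((t_start, value), ...) sorted by time."""

    steps: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.steps:
            raise ScenarioConfigError("setpoint profile needs at least one step")
        times = [t for t, _ in self.steps]
        if sorted(times) != times:
            raise ScenarioConfigError("setpoint steps must be time-sorted")
        if any(v < 0 for _, v in self.steps):
            raise ScenarioConfigError("setpoints must be >= 0")

    def value_at(self, t: float) -> float | None:
        """Setpoint in force at ``t``; None before the first step."""
        current = None
        for ts, v in self.steps:
            if ts <= t + 1e-12:
                current = v
        return current


@dataclass
class Scenario:
    """Everything needed to reproduce one simulated cultivation run."""

    scenario_id: str
    controller: str
    horizon: float
    initial: PlantState = field(default_factory=PlantState)
    params: PlantParams = field(default_factory=PlantParams)
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    seed: int = 0
    control_interval: float = 1.0
    glucose_setpoints: SetpointProfile | None = None
    nitrate_setpoints: SetpointProfile | None = None
    pid_gains: PidGains = field(default_factory=PidGains)
    controller_mu: float = C.MU_DARK        # nominal model μ for gmpc-setpoint
    refeed_threshold: float = 20.0          # mg/L, fed-batch exhaustion trigger
    refeed_bolus: float = 500.0             # mg/L, fed-batch bolus size
    fit_mode: str = "linked"
    mu_a_nominal: float = 0.020

    def __post_init__(self):
        if self.controller not in CONTROLLERS:
            raise ScenarioConfigError(
                f"unknown controller '{self.controller}'; choose from {CONTROLLERS}"
            )
        if self.horizon <= 0:
            raise ScenarioConfigError("horizon must be > 0")
        if self.control_interval <= 0:
            raise ScenarioConfigError("control interval must be > 0")


@dataclass
class ControlMetrics:
    """Summary metrics for a scenario run.

    Total absolute setpoint errors are summed over the control instants
    (mg·L⁻¹); masses are whole-reactor mg so that conservation can be checked
    exactly under dilution; yields are g biomass per g glucose, ``None`` when
    the denominator is zero (undefined marker).
    """

    total_abs_error_g: float | None
    total_abs_error_n: float | None
    residuals: list[dict]              # per phase end: t, phase, G, N (mg/L)
    fed_g: float                       # mg fed, whole reactor
    fed_n: float
    consumed_g: float                  # mg consumed, whole reactor
    consumed_n: float
    initial_g: float                   # mg at t0
    final_g: float                     # mg at horizon
    initial_n: float
    final_n: float
    delta_biomass: float               # g DW, whole reactor
    yield_on_fed: float | None         # gDW per g glucose fed
    yield_on_consumed: float | None    # gDW per g glucose consumed

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def _measure(state: PlantState, rng: np.random.Generator | None, params: PlantParams) -> Measurement:
    x_mg = state.x * 1000.0
    if rng is None:
        return Measurement(t=state.t, x_m=x_mg, g_m=state.g, n_m=state.n)
    return Measurement(
        t=state.t,
        x_m=max(x_mg + rng.normal(0.0, params.sigma_x), 0.0),
        g_m=max(state.g + rng.normal(0.0, params.sigma_g), 0.0),
        n_m=max(state.n + rng.normal(0.0, params.sigma_n), 0.0),
    )


def _nominal_fit(sc: Scenario) -> DarkFit:
    """Pre-measurement dark-cycle parameters: pure heterotrophic growth at the
    reference rate with rate-map exchanges."""
    rm = sc.params.ratemap
    return DarkFit(
        a=0.0, mu_a=sc.mu_a_nominal, mu_h=C.MU_DARK,
        r_na=rm.r_n_light(sc.mu_a_nominal), r_nh=rm.r_n_dark(C.MU_DARK),
        r_gh=rm.r_g_dark(C.MU_DARK), j=0.0, mode="nominal",
    )


def run_scenario(sc: Scenario) -> tuple[Trajectory, pd.DataFrame, ControlMetrics]:
    """Execute a scenario; returns (trajectory, control log, metrics).

    Deterministic given the scenario seed: reruns produce byte-identical
    CSV output.
    """
    rng = np.random.default_rng(sc.seed)
    noisy = any((sc.params.sigma_x, sc.params.sigma_g, sc.params.sigma_n))
    meas_rng = rng if noisy else None

    if sc.controller == "open-loop":
        cfg = OpenLoopConfig(
            ratemap=sc.params.ratemap, x0=sc.initial.x,
            g0=sc.initial.g, n0=sc.initial.n,
            mw_glucose=sc.params.mw_glucose, mw_nitrate=sc.params.mw_nitrate,
        )
        events = plan_feeds(cfg, sc.schedule, sc.horizon)
        traj = integrate(sc.initial, sc.schedule, events, sc.horizon, sc.params)
        log = _log_from_events(events, sc)
        return traj, log, compute_metrics(traj, sc, log)

    if sc.controller in ("pid", "gmpc-setpoint"):
        instants = _regular_instants(sc)
        traj, log = _run_feedback_loop(sc, instants, meas_rng)
    elif sc.controller == "fed-batch":
        instants = _regular_instants(sc)
        traj, log = _run_feedback_loop(sc, instants, meas_rng)
    else:  # closed-loop
        traj, log = _run_cycle_loop(sc, meas_rng)
    return traj, log, compute_metrics(traj, sc, log)


def _regular_instants(sc: Scenario) -> list[float]:
    n = int(round(sc.horizon / sc.control_interval))
    if abs(n * sc.control_interval - sc.horizon) > 1e-9:
        n = int(math.floor(sc.horizon / sc.control_interval))
    return [i * sc.control_interval for i in range(n + 1)]


def _run_feedback_loop(
    sc: Scenario, instants: Sequence[float], rng: np.random.Generator | None
) -> tuple[Trajectory, pd.DataFrame]:
    state = sc.initial
    parts: list[Trajectory] = []
    cons_off = np.zeros(2)
    rows: list[dict] = []
    pid_g, pid_n = PidState(), PidState()
    # Measurement-adapted growth-rate estimates for the gmpc-setpoint law:
    # start at the nominal model rate, then refit from observed consumption
    # (the feedback path that compensates modeling error).
    mu_hat_g = mu_hat_n = sc.controller_mu
    prev_m: Measurement | None = None
    prev_fg = prev_fn = 0.0
    rm = sc.params.ratemap

    for k, t in enumerate(instants):
        m = _measure(state, rng, sc.params)
        if sc.controller == "gmpc-setpoint" and prev_m is not None and prev_m.x_m > 0:
            dt_prev = t - prev_m.t
            x_prev = prev_m.x_m / 1000.0
            cons_g_obs = max(prev_m.g_m + prev_fg - m.g_m, 0.0)
            cons_n_obs = max(prev_m.n_m + prev_fn - m.n_m, 0.0)
            mu_hat_g = estimate_mu_from_consumption(
                cons_g_obs, x_prev, dt_prev, rm.g_coeff_dark, sc.params.mw_glucose)
            mu_hat_n = estimate_mu_from_consumption(
                cons_n_obs, x_prev, dt_prev, rm.n_coeff_dark, sc.params.mw_nitrate)
        sp_g = sc.glucose_setpoints.value_at(t) if sc.glucose_setpoints else None
        sp_n = sc.nitrate_setpoints.value_at(t) if sc.nitrate_setpoints else None
        f_g = f_n = 0.0
        last = k == len(instants) - 1
        if not last:
            dt = instants[k + 1] - t
            if sc.controller == "pid":
                if sp_g is not None:
                    f_g, pid_g = pid_step(pid_g, sc.pid_gains, sp_g, m.g_m, dt)
                if sp_n is not None:
                    f_n, pid_n = pid_step(pid_n, sc.pid_gains, sp_n, m.n_m, dt)
            elif sc.controller == "gmpc-setpoint":
                if sp_g is not None:
                    f_g = setpoint_feed(
                        m, sp_g, sc.params.ratemap, "glucose",
                        mu=mu_hat_g, horizon=dt,
                        mw_glucose=sc.params.mw_glucose, mw_nitrate=sc.params.mw_nitrate,
                    )
                if sp_n is not None:
                    f_n = setpoint_feed(
                        m, sp_n, sc.params.ratemap, "nitrate",
                        mu=mu_hat_n, horizon=dt,
                        mw_glucose=sc.params.mw_glucose, mw_nitrate=sc.params.mw_nitrate,
                    )
            else:  # fed-batch
                if m.g_m <= sc.refeed_threshold:
                    f_g = sc.refeed_bolus
        rows.append({
            "t": t, "phase": sc.schedule.phase_at(t).value,
            "x_m": m.x_m, "G_m": m.g_m, "N_m": m.n_m,
            "sp_G": np.nan if sp_g is None else sp_g,
            "sp_N": np.nan if sp_n is None else sp_n,
            "F_G": f_g, "F_N": f_n,
        })
        if last:
            break
        prev_m, prev_fg, prev_fn = m, f_g, f_n
        event = [BolusEvent(time=t, f_g=f_g, f_n=f_n)] if (f_g or f_n) else []
        part = integrate(state, sc.schedule, event, instants[k + 1] - t, sc.params)
        part.frame[["cons_G", "cons_N"]] += cons_off
        cons_off = part.frame[["cons_G", "cons_N"]].iloc[-1].to_numpy()
        state = part.final_state()
        parts.append(part)

    return Trajectory.concatenate(parts), pd.DataFrame(rows)


def _run_cycle_loop(
    sc: Scenario, rng: np.random.Generator | None
) -> tuple[Trajectory, pd.DataFrame]:
    """Cycle-wise closed-loop GMPC: feed at phase starts, fit each dark cycle."""
    state = sc.initial
    ctrl = ControllerState(ratemap=sc.params.ratemap, shading=ShadingLaw(
        mu0=sc.params.mu0_light, k=sc.params.k_shading))
    parts: list[Trajectory] = []
    cons_off = np.zeros(2)
    rows: list[dict] = []
    pending: tuple[Measurement, BolusEvent] | None = None  # last dark start

    segs = list(sc.schedule.segments(0.0, sc.horizon))
    for start, end, mode in segs:
        m = _measure(state, rng, sc.params)
        if pending is not None:
            # The dark cycle that began at `pending` just ended: fit it.
            m0, fed = pending
            demand = calc_demand(m0, m, fed)
            if demand.mu_c > 0:
                ctrl.fit = fit_dark_cycle(
                    demand, sc.params.ratemap, mode=sc.fit_mode,
                    mu_a_nominal=sc.mu_a_nominal,
                    mw_glucose=sc.params.mw_glucose, mw_nitrate=sc.params.mw_nitrate,
                )
            pending = None
        if mode is GrowthMode.DARK:
            fit = ctrl.fit if ctrl.fit is not None else _nominal_fit(sc)
            event = predict_dark_feed(
                fit, m.x_m / 1000.0, end - start, time=start,
                mw_glucose=sc.params.mw_glucose, mw_nitrate=sc.params.mw_nitrate,
            )
            pending = (m, event)
        else:
            event = predict_light_feed(
                m.x_m, sc.params.ratemap, end - start, ctrl.shading,
                time=start, mw_nitrate=sc.params.mw_nitrate,
            )
        rows.append({
            "t": start, "phase": mode.value,
            "x_m": m.x_m, "G_m": m.g_m, "N_m": m.n_m,
            "sp_G": np.nan, "sp_N": np.nan,
            "F_G": event.f_g, "F_N": event.f_n,
        })
        part = integrate(state, sc.schedule, [event], end - start, sc.params)
        part.frame[["cons_G", "cons_N"]] += cons_off
        cons_off = part.frame[["cons_G", "cons_N"]].iloc[-1].to_numpy()
        state = part.final_state()
        parts.append(part)
        ctrl.last_measurement = m
        ctrl.last_feed = event

    return Trajectory.concatenate(parts), pd.DataFrame(rows)


def _log_from_events(events: Sequence[BolusEvent], sc: Scenario) -> pd.DataFrame:
    rows = [{
        "t": e.time, "phase": sc.schedule.phase_at(e.time).value,
        "x_m": np.nan, "G_m": np.nan, "N_m": np.nan,
        "sp_G": np.nan, "sp_N": np.nan, "F_G": e.f_g, "F_N": e.f_n,
    } for e in events]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def compute_metrics(
    traj: Trajectory, sc: Scenario, control_log: pd.DataFrame | None = None
) -> ControlMetrics:
    """Integrated setpoint errors, phase-end residuals, feed totals and yields."""
    if traj.frame.empty:
        raise ValueError("trajectory is empty")

    def total_error(meas_col: str, sp_col: str) -> float | None:
        if control_log is None or control_log.empty:
            return None
        sub = control_log.dropna(subset=[sp_col, meas_col])
        if sub.empty:
            return None
        return float((sub[meas_col] - sub[sp_col]).abs().sum())

    residuals = []
    for _, seg_end, mode in sc.schedule.segments(0.0, sc.horizon):
        if seg_end <= traj.t_end + 1e-9:
            st = traj.state_at(min(seg_end, traj.t_end))
            g, n, v = st.g, st.n, st.v
            # boundary rows reflect the next phase's bolus; undo it so the
            # residual is what the ending phase actually left behind
            for e in traj.events:
                if abs(e.time - seg_end) < 1e-9:
                    v_pre = v - (e.added_volume or 0.0)
                    g = max((g * v - e.f_g * v_pre) / v_pre, 0.0)
                    n = max((n * v - e.f_n * v_pre) / v_pre, 0.0)
                    v = v_pre
            residuals.append({"t": seg_end, "phase": mode.value, "G": g, "N": n})

    last = traj.frame.iloc[-1]
    fed_g = fed_n = 0.0
    for e in traj.events:
        dv = e.added_volume or 0.0
        v_after = traj.state_at(e.time).v
        v_before = v_after - dv if sc.params.dilution else v_after
        fed_g += e.f_g * v_before
        fed_n += e.f_n * v_before
    consumed_g, consumed_n = traj.consumed()
    # Initial masses come from the scenario's pre-run state so that boluses
    # applied at t = 0 are counted once (as feeds).
    init = sc.initial
    initial_g = init.g * init.v
    final_g = float(last["G"] * last["V"])
    initial_n = init.n * init.v
    final_n = float(last["N"] * last["V"])
    delta_x = float(last["x"] * last["V"]) - init.x * init.v  # g DW

    def _yield(denom_mg: float) -> float | None:
        return None if denom_mg <= 0 else delta_x / (denom_mg / 1000.0)

    return ControlMetrics(
        total_abs_error_g=total_error("G_m", "sp_G"),
        total_abs_error_n=total_error("N_m", "sp_N"),
        residuals=residuals,
        fed_g=fed_g, fed_n=fed_n,
        consumed_g=consumed_g, consumed_n=consumed_n,
        initial_g=initial_g, final_g=final_g,
        initial_n=initial_n, final_n=final_n,
        delta_biomass=delta_x,
        yield_on_fed=_yield(fed_g),
        yield_on_consumed=_yield(consumed_g),
    )


# ---------------------------------------------------------------------------
# Config I/O and outputs
# ---------------------------------------------------------------------------

_SCHEDULE_MODES = {"light": GrowthMode.LIGHT, "dark": GrowthMode.DARK}


def scenario_from_yaml(path: str | Path) -> Scenario:
    """Load a scenario from a YAML config file (see docs for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ScenarioConfigError(f"{path}: top level must be a mapping")
    return scenario_from_dict(raw)


def scenario_from_dict(raw: dict[str, Any]) -> Scenario:
    known = {
        "id", "controller", "horizon", "seed", "control_interval", "schedule",
        "initial", "params", "setpoints", "pid", "controller_mu",
        "refeed_threshold", "refeed_bolus", "fit_mode", "mu_a_nominal",
    }
    unknown = set(raw) - known
    if unknown:
        raise ScenarioConfigError(f"unknown config keys: {sorted(unknown)}")
    for req in ("id", "controller", "horizon"):
        if req not in raw:
            raise ScenarioConfigError(f"missing required config key '{req}'")

    sched_raw = raw.get("schedule")
    if sched_raw is None:
        schedule = PhaseSchedule()
    elif "constant" in sched_raw:
        mode = _SCHEDULE_MODES.get(str(sched_raw["constant"]).lower())
        if mode is None:
            raise ScenarioConfigError(f"unknown mode '{sched_raw['constant']}'")
        schedule = PhaseSchedule.constant(mode, float(sched_raw.get("period", 8.0)))
    else:
        blocks = []
        for entry in sched_raw.get("blocks", []):
            mode = _SCHEDULE_MODES.get(str(entry[0]).lower())
            if mode is None:
                raise ScenarioConfigError(f"unknown mode '{entry[0]}'")
            blocks.append((mode, float(entry[1])))
        schedule = PhaseSchedule(blocks=tuple(blocks))

    init_raw = raw.get("initial", {})
    initial = PlantState(
        t=0.0,
        x=float(init_raw.get("x", 0.1)),
        g=float(init_raw.get("g", 0.0)),
        n=float(init_raw.get("n", 0.0)),
        v=float(init_raw.get("v", 2.0)),
    )
    params_raw = dict(raw.get("params", {}))
    try:
        params = replace(PlantParams(), **params_raw)
    except TypeError as exc:
        raise ScenarioConfigError(f"bad plant params: {exc}") from exc

    def profile(key: str) -> SetpointProfile | None:
        sp = raw.get("setpoints", {}) or {}
        if key not in sp or sp[key] is None:
            return None
        return SetpointProfile(tuple((float(t), float(v)) for t, v in sp[key]))

    pid_raw = raw.get("pid", {}) or {}
    gains = PidGains(
        kp=float(pid_raw.get("kp", C.PID_KP)),
        ki=float(pid_raw.get("ki", C.PID_KI)),
        kd=float(pid_raw.get("kd", C.PID_KD)),
        integral_limit=float(pid_raw.get("integral_limit", math.inf)),
    )
    return Scenario(
        scenario_id=str(raw["id"]),
        controller=str(raw["controller"]),
        horizon=float(raw["horizon"]),
        initial=initial,
        params=params,
        schedule=schedule,
        seed=int(raw.get("seed", 0)),
        control_interval=float(raw.get("control_interval", 1.0)),
        glucose_setpoints=profile("glucose"),
        nitrate_setpoints=profile("nitrate"),
        pid_gains=gains,
        controller_mu=float(raw.get("controller_mu", C.MU_DARK)),
        refeed_threshold=float(raw.get("refeed_threshold", 20.0)),
        refeed_bolus=float(raw.get("refeed_bolus", 500.0)),
        fit_mode=str(raw.get("fit_mode", "linked")),
        mu_a_nominal=float(raw.get("mu_a_nominal", 0.020)),
    )


def write_outputs(
    outdir: str | Path,
    sc: Scenario,
    traj: Trajectory,
    control_log: pd.DataFrame,
    metrics: ControlMetrics,
) -> None:
    """Write trajectory CSV, feed-log CSV, metrics JSON and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj.to_csv(outdir / f"{sc.scenario_id}_trajectory.csv")
    feed_rows = [{
        "t": e.time, "F_G": e.f_g, "F_N": e.f_n,
        "t_pump_G": e.t_pump_g, "t_pump_N": e.t_pump_n,
    } for e in traj.events]
    pd.DataFrame(feed_rows).to_csv(outdir / f"{sc.scenario_id}_feeds.csv", index=False)
    control_log.to_csv(outdir / f"{sc.scenario_id}_control.csv", index=False)
    with open(outdir / f"{sc.scenario_id}_metrics.json", "w") as fh:
        json.dump(metrics.to_dict(), fh, indent=2)
    desc = repr(sc).encode()
    with open(outdir / f"{sc.scenario_id}_runlog.json", "w") as fh:
        json.dump({
            "scenario_id": sc.scenario_id,
            "seed": sc.seed,
            "config_sha256": hashlib.sha256(desc).hexdigest(),
        }, fh, indent=2)


# ---------------------------------------------------------------------------
# Shipped scenario factories
# ---------------------------------------------------------------------------

def pid_comparison_scenario(controller: str, seed: int = 0) -> Scenario:
    """Hourly setpoint-tracking comparison on a dark heterotrophic reactor.

    Glucose setpoint 40 → 20 mg/L at 20 h, nitrate 20 → 10 mg/L at 35 h,
    50 h horizon, 1 h control interval, initial biomass 0.4 gDW/L (the
    density of the reference experimental comparison).  The plant is
    simulated noiselessly (a deterministic numerical experiment); the
    controller's model still mismatches the plant through its Monod
    saturation terms, which the feedback path must absorb.
    """
    if controller not in ("pid", "gmpc-setpoint"):
        raise ScenarioConfigError("controller must be 'pid' or 'gmpc-setpoint'")
    params = PlantParams(sigma_x=0.0, sigma_g=0.0, sigma_n=0.0)
    return Scenario(
        scenario_id=f"setpoint-{controller}",
        controller=controller,
        horizon=50.0,
        initial=PlantState(t=0.0, x=0.4, g=40.0, n=20.0, v=2.0),
        params=params,
        schedule=PhaseSchedule.constant(GrowthMode.DARK),
        seed=seed,
        control_interval=1.0,
        glucose_setpoints=SetpointProfile(((0.0, 40.0), (20.0, 20.0))),
        nitrate_setpoints=SetpointProfile(((0.0, 20.0), (35.0, 10.0))),
    )


def fed_batch_scenario(seed: int = 0) -> Scenario:
    """Dark-phase fed-batch baseline: 500 mg/L bolus refeeds at exhaustion."""
    return Scenario(
        scenario_id="fed-batch",
        controller="fed-batch",
        horizon=96.0,
        initial=PlantState(t=0.0, x=0.1, g=500.0, n=200.0, v=2.0),
        params=PlantParams(),
        schedule=PhaseSchedule.constant(GrowthMode.DARK),
        seed=seed,
        control_interval=8.0,
    )


def open_loop_scenario(seed: int = 0) -> Scenario:
    """Open-loop cycling culture: 16 h light / 8 h dark, 96 h."""
    return Scenario(
        scenario_id="open-loop",
        controller="open-loop",
        horizon=96.0,
        initial=PlantState(t=0.0, x=0.1, g=0.0, n=30.0, v=2.0),
        params=PlantParams(),
        schedule=PhaseSchedule(),
        seed=seed,
    )


def closed_loop_scenario(seed: int = 0, a_true: float = 0.0) -> Scenario:
    """Closed-loop cycling culture with per-cycle dark fits, 96 h."""
    return Scenario(
        scenario_id="closed-loop",
        controller="closed-loop",
        horizon=96.0,
        initial=PlantState(t=0.0, x=0.035, g=10.0, n=50.0, v=2.0),
        params=PlantParams(a_true=a_true),
        schedule=PhaseSchedule(),
        seed=seed,
    )


def setpoint_tracking_comparison(seed: int = 0) -> dict[str, float]:
    """Run PID and GMPC on the same seeded setpoint-step plant and summarize.

    Returns post-step total absolute errors per controller and species, the
    relative error reduction achieved by GMPC ((PID − GMPC)/PID·100, %), and
    the maximum hourly nitrate deviation under GMPC after 44 h (the settled
    regime following the 35 h setpoint step).
    """
    out: dict[str, float] = {}
    logs = {}
    for ctrl in ("pid", "gmpc-setpoint"):
        sc = pid_comparison_scenario(ctrl, seed=seed)
        _, log, _ = run_scenario(sc)
        logs[ctrl] = log
        tag = "pid" if ctrl == "pid" else "gmpc"
        post_g = log[log.t > 20.0]
        post_n = log[log.t > 35.0]
        out[f"{tag}_err_glucose"] = float((post_g.G_m - post_g.sp_G).abs().sum())
        out[f"{tag}_err_nitrate"] = float((post_n.N_m - post_n.sp_N).abs().sum())
    late = logs["gmpc-setpoint"]
    late = late[late.t > 44.0]
    out["gmpc_max_nitrate_dev_after_44h"] = float((late.N_m - late.sp_N).abs().max())
    for sp in ("glucose", "nitrate"):
        pid_e, gm_e = out[f"pid_err_{sp}"], out[f"gmpc_err_{sp}"]
        out[f"reduction_{sp}_pct"] = 100.0 * (pid_e - gm_e) / pid_e if pid_e else math.nan
    return out


def shipped_scenarios(seed: int = 0) -> dict[str, Scenario]:
    """All packaged reference scenarios keyed by id."""
    out = {}
    for sc in (
        fed_batch_scenario(seed),
        open_loop_scenario(seed),
        closed_loop_scenario(seed),
        pid_comparison_scenario("pid", seed),
        pid_comparison_scenario("gmpc-setpoint", seed),
    ):
        out[sc.scenario_id] = sc
    return out
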