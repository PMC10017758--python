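"""Closed-loop controller: measurement-derived rates, the dark-cycle
mixed-metabolism fit, the light-cycle shading predictor, and an hourly
setpoint-tracking law for the PID comparison.

Dark cycles assume two co-existing metabolic modes: a fraction ``a`` of the
biomass grows autotrophically (CO₂-fixing, rate μ_A) while the rest grows
heterotrophically on glucose (rate μ_H), so

    μ_model = a·μ_A + μ_H
    F_N,model = a·F_NA + F_NH          F_G,model from r_GH

Measured (x_m, G_m, N_m) pairs 8 h apart give the calculated growth rate
μ_c = ln(x_t/x_{t−8})/8 and consumed substrate per litre (F_GC, F_NC).  The
fit minimizes the relative squared mismatch

    J = ((μ_model−μ_c)/μ_c)² + ((F_G,model−F_GC)/F_GC)² + ((F_N,model−F_NC)/F_NC)²

over the mixed-metabolism parameters; the optimum dictates the next cycle's
feeds.  Light cycles use the biomass-shading growth law μ(x) = μ₀·e^{−kx}
with the rate map to size the nitrate bolus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import constants as C
from .errors import FitError
from .openloop import bolus_demand
from .plant import BolusEvent, Measurement
from .ratemap import RateMap

__all__ = [
    "ShadingLaw",
    "CalculatedDemand",
    "DarkFit",
    "ControllerState",
    "calc_demand",
    "fit_dark_cycle",
    "predict_dark_feed",
    "predict_light_feed",
    "setpoint_feed",
]

#: Below this magnitude a relative J denominator switches to absolute form.
DENOM_EPS = 1e-6


@dataclass(frozen=True)
class ShadingLaw:
    """Biomass-density growth decay in the light: μ(x) = μ₀·exp(−k·x[mg/L])."""

    mu0: float = C.SHADING_MU0   # h⁻¹
    k: float = C.SHADING_K       # per mg·L⁻¹

    def mu_at(self, x_mg_per_l: float) -> float:
        """Shaded growth rate at biomass density ``x_mg_per_l`` (mg·L⁻¹)."""
        if x_mg_per_l < 0:
            raise ValueError("biomass must be >= 0")
        return self.mu0 * math.exp(-self.k * x_mg_per_l)


@dataclass(frozen=True)
class CalculatedDemand:
    """Measurement-derived growth rate and consumed substrate over an interval.

    Demands follow the consumption convention: mass consumed per litre over
    the interval, bolus feeds included, floored at 0.
    """

    mu_c: float      # h⁻¹
    f_gc: float      # mg·L⁻¹ glucose consumed
    f_nc: float      # mg·L⁻¹ nitrate consumed
    interval: float  # h
    x_start: float   # gDW·L⁻¹ biomass at interval start


@dataclass(frozen=True)
class DarkFit:
    """Fitted dark-cycle mixed-metabolism parameters and achieved objective."""

    a: float         # autotrophic biomass fraction, dimensionless
    mu_a: float      # h⁻¹
    mu_h: float      # h⁻¹
    r_na: float      # mmol nitrate·gDW⁻¹·h⁻¹ (autotrophic)
    r_nh: float      # mmol nitrate·gDW⁻¹·h⁻¹ (heterotrophic)
    r_gh: float      # mmol glucose·gDW⁻¹·h⁻¹ (heterotrophic)
    j: float         # achieved objective (tether excluded)
    flags: tuple[str, ...] = ()
    mode: str = "linked"

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("fitted fraction a must lie in [0, 1]")
        if min(self.mu_a, self.mu_h, self.r_na, self.r_nh, self.r_gh) < 0:
            raise ValueError("fitted rates must be >= 0")
        if self.j < 0:
            raise ValueError("objective must be >= 0")

    @property
    def mu_model(self) -> float:
        return self.a * self.mu_a + self.mu_h


@dataclass
class ControllerState:
    """Carry-over state for the cycling closed-loop controller."""

    ratemap: RateMap
    shading: ShadingLaw = field(default_factory=ShadingLaw)
    last_measurement: Measurement | None = None
    last_feed: BolusEvent | None = None
    fit: DarkFit | None = None


# ---------------------------------------------------------------------------
# Measurement-derived demand
# ---------------------------------------------------------------------------

def calc_demand(
    m_prev: Measurement, m_now: Measurement, fed: BolusEvent | None = None
) -> CalculatedDemand:
    """Growth rate and consumed substrate between two measurements.

    μ_c = ln(x_now/x_prev)/Δt.  Consumption includes what was fed during the
    interval: F_GC = (G_prev + fed glucose) − G_now, floored at 0 (likewise
    nitrate) — the magnitude convention keeps J's denominators positive.
    """
    dt = m_now.t - m_prev.t
    if dt <= 0:
        raise ValueError("measurements must be in increasing time order")
    if m_prev.x_m <= 0 or m_now.x_m <= 0:
        raise ValueError("biomass measurements must be > 0 to compute a growth rate")
    fed_g = fed.f_g if fed else 0.0
    fed_n = fed.f_n if fed else 0.0
    return CalculatedDemand(
        mu_c=math.log(m_now.x_m / m_prev.x_m) / dt,
        f_gc=max(m_prev.g_m + fed_g - m_now.g_m, 0.0),
        f_nc=max(m_prev.n_m + fed_n - m_now.n_m, 0.0),
        interval=dt,
        x_start=m_prev.x_m / 1000.0,
    )


# ---------------------------------------------------------------------------
# Dark-cycle fit
# ---------------------------------------------------------------------------

def model_demands(
    a: float,
    mu_a: float,
    mu_h: float,
    r_na: float,
    r_nh: float,
    r_gh: float,
    x0: float,
    interval: float,
    mw_glucose: float = C.MW_GLUCOSE,
    mw_nitrate: float = C.MW_NITRATE,
) -> tuple[float, float, float]:
    """(μ_model, F_G,model, F_N,model) for mixed-metabolism dark growth.

    Demands are the bolus integral with biomass growing at μ_model:
    F_N,model = a·F_NA + F_NH collapses to a single integral because every
    biomass fraction grows with the same total rate.
    """
    mu_model = a * mu_a + mu_h
    f_g = bolus_demand(x0, mu_model, r_gh, interval, mw_glucose)
    f_n = bolus_demand(x0, mu_model, a * r_na + r_nh, interval, mw_nitrate)
    return mu_model, f_g, f_n


def objective_terms(
    demand: CalculatedDemand,
    mu_model: float,
    f_g_model: float,
    f_n_model: float,
) -> tuple[float, tuple[str, ...]]:
    """J and the names of any terms that fell back to absolute form.

    Each term is ((model − calculated)/calculated)²; a calculated denominator
    with magnitude ≤ DENOM_EPS switches that term to absolute squared error.
    """
    flags: list[str] = []
    j = 0.0
    for name, model, calc in (
        ("mu", mu_model, demand.mu_c),
        ("f_g", f_g_model, demand.f_gc),
        ("f_n", f_n_model, demand.f_nc),
    ):
        if abs(calc) <= DENOM_EPS:
            j += (model - calc) ** 2
            flags.append(name)
        else:
            j += ((model - calc) / calc) ** 2
    return j, tuple(flags)


def fit_dark_cycle(
    demand: CalculatedDemand,
    ratemap: RateMap,
    interval: float | None = None,
    x_start: float | None = None,
    *,
    mode: str = "linked",
    mu_a_nominal: float = 0.020,
    n_starts: int = 8,
    seed: int = 0,
    tether: float = 1e-6,
    mw_glucose: float = C.MW_GLUCOSE,
    mw_nitrate: float = C.MW_NITRATE,
) -> DarkFit:
    """Fit the mixed-metabolism parameters minimizing J for one dark cycle.

    ``mode="linked"`` (default) optimizes (a, μ_A, μ_H) with each exchange
    rate tied to its growth rate through the rate map — the genome-scale
    consistency constraint.  ``mode="free"`` optimizes all six parameters
    independently inside box bounds [0, 2× anchor].

    Because J depends on a and μ_A only through the product a·μ_A, the fit
    adds a tiny quadratic tether (weight ``tether``) pulling μ_A toward
    ``mu_a_nominal`` — the autotrophic growth rate the genome-scale model
    predicts at the minimal dark-phase light level — which selects a unique
    point on the otherwise flat ridge.  The reported J excludes the tether.

    The search is a deterministic multi-start bounded quasi-Newton
    (``n_starts`` seeded draws plus a nominal and an analytic warm start).
    """
    interval = demand.interval if interval is None else interval
    x0 = demand.x_start if x_start is None else x_start
    if x0 is None or x0 <= 0:
        raise ValueError("biomass at cycle start must be > 0")
    if not all(map(math.isfinite, (demand.mu_c, demand.f_gc, demand.f_nc))):
        raise ValueError("calculated demand fields must be finite")
    if mode not in ("linked", "free"):
        raise ValueError(f"unknown fit mode '{mode}'")

    mu_a_hi, mu_h_hi = 2.0 * C.MU_LIGHT, 2.0 * C.MU_DARK

    def unpack(theta):
        if mode == "linked":
            a, mu_a, mu_h = theta
            return (a, mu_a, mu_h, ratemap.r_n_light(mu_a),
                    ratemap.r_n_dark(mu_h), ratemap.r_g_dark(mu_h))
        return tuple(theta)

    def penalized(theta):
        a, mu_a, mu_h, r_na, r_nh, r_gh = unpack(theta)
        mu_m, f_g, f_n = model_demands(
            a, mu_a, mu_h, r_na, r_nh, r_gh, x0, interval, mw_glucose, mw_nitrate
        )
        j, _ = objective_terms(demand, mu_m, f_g, f_n)
        return j + tether * ((mu_a - mu_a_nominal) / mu_a_nominal) ** 2

    # Analytic warm start: pin mu_model to mu_c, read mu_h off F_GC, put the
    # remainder of the growth on the autotrophic fraction at nominal mu_A.
    growth_int = math.expm1(max(demand.mu_c, 0.0) * interval) / demand.mu_c \
        if demand.mu_c > 0 else interval
    denom = mw_glucose * ratemap.g_coeff_dark * x0 * growth_int
    mu_h_warm = min(max(demand.f_gc / denom, 0.0), mu_h_hi) if denom > 0 else C.MU_DARK
    a_warm = min(max((demand.mu_c - mu_h_warm) / mu_a_nominal, 0.0), 1.0)

    if mode == "linked":
        bounds = [(0.0, 1.0), (0.0, mu_a_hi), (0.0, mu_h_hi)]
        starts = [
            np.array([a_warm, mu_a_nominal, mu_h_warm]),
            np.array([0.2, mu_a_nominal, C.MU_DARK]),
        ]
    else:
        bounds = [(0.0, 1.0), (0.0, mu_a_hi), (0.0, mu_h_hi),
                  (0.0, 2.0 * C.R_N_LIGHT), (0.0, 2.0 * C.R_N_DARK),
                  (0.0, 2.0 * C.R_G_DARK)]
        starts = [
            np.array([a_warm, mu_a_nominal, mu_h_warm,
                      ratemap.r_n_light(mu_a_nominal), ratemap.r_n_dark(mu_h_warm),
                      ratemap.r_g_dark(mu_h_warm)]),
            np.array([0.2, mu_a_nominal, C.MU_DARK,
                      C.R_N_LIGHT, C.R_N_DARK, C.R_G_DARK]),
        ]
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    for _ in range(n_starts):
        starts.append(lo + rng.random(len(bounds)) * (hi - lo))

    best = None
    for theta0 in starts:
        res = minimize(
            penalized, theta0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-16, "gtol": 1e-12, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitError("dark-cycle fit did not converge to finite parameters")

    a, mu_a, mu_h, r_na, r_nh, r_gh = unpack(best.x)
    mu_m, f_g, f_n = model_demands(
        a, mu_a, mu_h, r_na, r_nh, r_gh, x0, interval, mw_glucose, mw_nitrate
    )
    j, flags = objective_terms(demand, mu_m, f_g, f_n)
    return DarkFit(
        a=float(np.clip(a, 0.0, 1.0)), mu_a=max(mu_a, 0.0), mu_h=max(mu_h, 0.0),
        r_na=max(r_na, 0.0), r_nh=max(r_nh, 0.0), r_gh=max(r_gh, 0.0),
        j=j, flags=flags, mode=mode,
    )


# ---------------------------------------------------------------------------
# Feed predictors
# ---------------------------------------------------------------------------

def predict_dark_feed(
    fit: DarkFit,
    x: float,
    interval: float,
    *,
    time: float = 0.0,
    mw_glucose: float = C.MW_GLUCOSE,
    mw_nitrate: float = C.MW_NITRATE,
) -> BolusEvent:
    """Bolus demands for the next dark interval from fitted parameters.

    ``x`` is the current biomass in gDW·L⁻¹; demands scale linearly with it.
    """
    if x <= 0:
        raise ValueError("biomass must be > 0")
    _, f_g, f_n = model_demands(
        fit.a, fit.mu_a, fit.mu_h, fit.r_na, fit.r_nh, fit.r_gh,
        x, interval, mw_glucose, mw_nitrate,
    )
    return BolusEvent(time=time, f_g=max(f_g, 0.0), f_n=max(f_n, 0.0))


def predict_light_feed(
    x_mg_per_l: float,
    ratemap: RateMap,
    interval: float,
    shading: ShadingLaw = ShadingLaw(),
    *,
    time: float = 0.0,
    mw_nitrate: float = C.MW_NITRATE,
) -> BolusEvent:
    """Nitrate bolus for a light interval; glucose is never fed in the light.

    The measured biomass density (mg·L⁻¹) sets the shaded growth rate, the
    rate map converts it to a nitrate exchange rate, and the demand integral
    sizes the bolus.
    """
    mu = shading.mu_at(x_mg_per_l)
    r_n = ratemap.r_n_light(mu)
    f_n = bolus_demand(x_mg_per_l / 1000.0, mu, r_n, interval, mw_nitrate)
    return BolusEvent(time=time, f_g=0.0, f_n=f_n)


def estimate_mu_from_consumption(
    consumed: float,
    x: float,
    interval: float,
    coeff: float,
    mw: float,
    *,
    mu_max: float = 2.0 * C.MU_DARK,
) -> float:
    """Invert the demand integral: growth rate implied by observed consumption.

    ``consumed`` is mg·L⁻¹ over ``interval`` h at biomass ``x`` (gDW·L⁻¹);
    ``coeff`` is the rate-map biomass coefficient (mmol·gDW⁻¹) for the
    consumed substrate.  Uses the short-interval linearization of the
    integral (exact as interval → 0) and clips to [0, mu_max].
    """
    if x <= 0 or interval <= 0 or coeff <= 0 or mw <= 0:
        raise ValueError("x, interval, coeff and mw must be > 0")
    mu = consumed / (mw * coeff * x * interval)
    return min(max(mu, 0.0), mu_max)


def setpoint_feed(
    m: Measurement,
    setpoint: float,
    ratemap: RateMap,
    species: str,
    *,
    mu: float | None = None,
    fit: DarkFit | None = None,
    horizon: float = 1.0,
    mw_glucose: float = C.MW_GLUCOSE,
    mw_nitrate: float = C.MW_NITRATE,
) -> float:
    """Hourly model-predictive feed (mg·L⁻¹) holding a substrate setpoint.

    feed = predicted consumption over ``horizon`` + (setpoint − measured),
    floored at 0 — the consumption forecast comes from the model, the
    correction term compensates modeling error.  Supply either a fixed
    heterotrophic growth rate ``mu`` or a :class:`DarkFit`.
    """
    if setpoint < 0:
        raise ValueError("setpoint must be >= 0")
    if species not in ("glucose", "nitrate"):
        raise ValueError(f"unknown species '{species}'")
    x0 = m.x_m / 1000.0
    if fit is not None:
        mu_model = fit.mu_model
        r = fit.r_gh if species == "glucose" else fit.a * fit.r_na + fit.r_nh
    elif mu is not None:
        mu_model = mu
        r = ratemap.r_g_dark(mu) if species == "glucose" else ratemap.r_n_dark(mu)
    else:
        raise ValueError("provide either a fixed mu or a DarkFit")
    mw = mw_glucose if species == "glucose" else mw_nitrate
    consumption = bolus_demand(x0, mu_model, r, horizon, mw)
    measured = m.g_m if species == "glucose" else m.n_m
    return max(consumption + (setpoint - measured), 0.0)
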