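"""Constraint-based model layer: stoichiometric models, FBA at fixed growth,
and the growth-rate → exchange-rate mapping used by every controller.

The central contract is :class:`RateMap`: given a growth mode (LIGHT =
autotrophic, DARK = heterotrophic) and a specific growth rate μ (h⁻¹), return
the specific glucose and nitrate exchange rates (mmol·gDW⁻¹·h⁻¹) the culture
needs.  The map can be backed either by a plain linear table (``provenance
"table"``) or by flux balance analysis on a stoichiometric model (``"fba"``).
Both routes are calibrated to the same anchor pairs — one printed (μ, r) pair
per mode — and agree by construction; tests assert the equivalence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import cobra
from cobra.io import load_json_model, read_sbml_model, save_json_model, write_sbml_model

from . import constants as C
from .errors import CalibrationError, InfeasibleGrowthError, ModelConfigError, ModelFormatError

__all__ = [
    "GrowthMode",
    "Anchor",
    "RateMap",
    "StoichModel",
    "FluxSolution",
    "DEFAULT_ANCHORS",
    "default_ratemap",
    "calibrate_toy_model",
    "toy_model",
    "load_model",
    "save_model",
    "solve_fba",
    "exchange_rates_at_mu",
]

#: Comparison tolerance for rate round-trips (anchors, linearity checks).
RATE_TOL = 1e-6

#: LP feasibility tolerance used when fixing fluxes between lexicographic stages.
LP_TOL = 1e-8


class GrowthMode(Enum):
    """Cultivation phase: LIGHT is autotrophic, DARK is heterotrophic."""

    LIGHT = "light"
    DARK = "dark"


class Anchor(NamedTuple):
    """A (mode, μ, r_G, r_N) calibration point for the exchange-rate map."""

    mode: GrowthMode
    mu: float           # h⁻¹
    r_g: float          # mmol glucose · gDW⁻¹ · h⁻¹ (0 in LIGHT)
    r_n: float          # mmol nitrate · gDW⁻¹ · h⁻¹


#: The printed anchor pairs: one per mode for nitrate, plus dark glucose.
DEFAULT_ANCHORS: tuple[Anchor, ...] = (
    Anchor(GrowthMode.LIGHT, C.MU_LIGHT, C.R_G_LIGHT, C.R_N_LIGHT),
    Anchor(GrowthMode.DARK, C.MU_DARK, C.R_G_DARK, C.R_N_DARK),
)


# ---------------------------------------------------------------------------
# RateMap (table mode)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateMap:
    """Linear growth-rate → exchange-rate map, r(μ) = coeff·μ + offset.

    Coefficients are in mmol·gDW⁻¹ (biomass-equation demands), offsets in
    mmol·gDW⁻¹·h⁻¹ (non-growth-associated maintenance, zero by default).
    Glucose is only exchanged in DARK (heterotrophic) mode.
    """

    n_coeff_light: float                 # mmol NO3 per gDW of autotrophic biomass
    n_coeff_dark: float                  # mmol NO3 per gDW of heterotrophic biomass
    g_coeff_dark: float                  # mmol glucose per gDW of heterotrophic biomass
    n_offset_light: float = 0.0
    n_offset_dark: float = 0.0
    g_offset_dark: float = 0.0
    provenance: str = "table"

    def __post_init__(self):
        for name in ("n_coeff_light", "n_coeff_dark", "g_coeff_dark",
                     "n_offset_light", "n_offset_dark", "g_offset_dark"):
            if getattr(self, name) < 0:
                raise ValueError(f"RateMap.{name} must be >= 0")

    @classmethod
    def from_anchors(cls, anchors: Iterable[Anchor]) -> "RateMap":
        """Build a linear-through-origin map from anchor pairs.

        Multiple anchors per mode must imply the same coefficients (within
        :data:`RATE_TOL` relative); otherwise a :class:`CalibrationError`
        is raised.
        """
        coeffs: dict[str, float] = {}

        def _set(key: str, value: float):
            if key in coeffs and not math.isclose(coeffs[key], value, rel_tol=RATE_TOL):
                raise CalibrationError(
                    f"inconsistent anchors for {key}: {coeffs[key]:g} vs {value:g}"
                )
            coeffs[key] = value

        seen_modes = set()
        for a in anchors:
            if a.mu <= 0:
                raise CalibrationError(f"anchor growth rate must be > 0, got {a.mu}")
            if a.r_n < 0 or a.r_g < 0:
                raise CalibrationError("anchor rates must be >= 0")
            seen_modes.add(a.mode)
            if a.mode is GrowthMode.LIGHT:
                if a.r_g > 0:
                    raise CalibrationError(
                        "LIGHT anchors must have r_G = 0 (no glucose uptake "
                        "under autotrophic growth)"
                    )
                _set("n_light", a.r_n / a.mu)
            else:
                _set("n_dark", a.r_n / a.mu)
                _set("g_dark", a.r_g / a.mu)
        if seen_modes != {GrowthMode.LIGHT, GrowthMode.DARK}:
            raise CalibrationError("need at least one anchor per growth mode")
        return cls(
            n_coeff_light=coeffs["n_light"],
            n_coeff_dark=coeffs["n_dark"],
            g_coeff_dark=coeffs["g_dark"],
        )

    # -- specific-rate accessors ------------------------------------------
    def r_n_light(self, mu: float) -> float:
        """Autotrophic nitrate uptake at growth rate ``mu`` (mmol·gDW⁻¹·h⁻¹)."""
        return self.n_coeff_light * mu + self.n_offset_light

    def r_n_dark(self, mu: float) -> float:
        """Heterotrophic nitrate uptake at growth rate ``mu``."""
        return self.n_coeff_dark * mu + self.n_offset_dark

    def r_g_dark(self, mu: float) -> float:
        """Heterotrophic glucose uptake at growth rate ``mu``."""
        return self.g_coeff_dark * mu + self.g_offset_dark

    def rates(self, mode: GrowthMode, mu: float) -> tuple[float, float]:
        """Return ``(r_G, r_N)`` at growth rate ``mu`` for the given mode."""
        if mu < 0:
            raise ValueError(f"growth rate must be >= 0, got {mu}")
        if mode is GrowthMode.LIGHT:
            return 0.0, self.n_coeff_light * mu + self.n_offset_light
        return self.r_g_dark(mu), self.r_n_dark(mu)


def default_ratemap() -> RateMap:
    """The table rate map calibrated to the printed anchor pairs."""
    return RateMap.from_anchors(DEFAULT_ANCHORS)


# ---------------------------------------------------------------------------
# Stoichiometric model (FBA mode)
# ---------------------------------------------------------------------------

#: Default designated-reaction identifiers used by the packaged toy model.
DEFAULT_IDS: Mapping[str, str] = {
    "biomass_light": "BIOMASS_light",
    "biomass_dark": "BIOMASS_dark",
    "glucose_exchange": "EX_glc__D_e",
    "nitrate_exchange": "EX_no3_e",
    "co2_exchange": "EX_co2_e",
    "photon_exchange": "EX_photon_e",
}


@dataclass
class StoichModel:
    """A cobra model plus the designated-reaction contract gmpc relies on.

    ``biomass`` maps each supported :class:`GrowthMode` to its biomass
    reaction id; ``exchanges`` names the glucose, nitrate, CO₂ and photon
    exchange reactions.  Designation is by explicit ids, never by name
    heuristics, so the same code drives the packaged toy model or a real
    genome-scale reconstruction.
    """

    model: cobra.Model
    biomass: dict[GrowthMode, str]
    exchanges: dict[str, str] = field(
        default_factory=lambda: {
            "glucose": DEFAULT_IDS["glucose_exchange"],
            "nitrate": DEFAULT_IDS["nitrate_exchange"],
            "co2": DEFAULT_IDS["co2_exchange"],
            "photon": DEFAULT_IDS["photon_exchange"],
        }
    )

    def __post_init__(self):
        self.validate()

    @property
    def modes(self) -> tuple[GrowthMode, ...]:
        return tuple(self.biomass)

    def validate(self) -> None:
        rxn_ids = {r.id for r in self.model.reactions}
        designated = list(self.biomass.values()) + list(self.exchanges.values())
        for rid in designated:
            if rid not in rxn_ids:
                raise ModelConfigError(f"designated reaction '{rid}' not in model")
        if len(set(designated)) != len(designated):
            raise ModelConfigError("designated reactions must be distinct")
        for r in self.model.reactions:
            if r.lower_bound > r.upper_bound:
                raise ModelConfigError(
                    f"reaction '{r.id}' has lower bound > upper bound"
                )

    def reaction(self, rid: str) -> cobra.Reaction:
        return self.model.reactions.get_by_id(rid)


@dataclass(frozen=True)
class FluxSolution:
    """An FBA solution: objective value, per-reaction fluxes, solver status."""

    objective: float
    fluxes: Mapping[str, float]
    status: str

    def uptake(self, exchange_id: str) -> float:
        """Uptake through an exchange reaction (positive = consumption)."""
        return -self.fluxes[exchange_id]


# ---------------------------------------------------------------------------
# Toy-model construction
# ---------------------------------------------------------------------------

def calibrate_toy_model(anchors: Sequence[Anchor] = DEFAULT_ANCHORS) -> StoichModel:
    """Build a small stoichiometric model whose FBA uptakes reproduce the anchors.

    The biomass equations are written with substrate coefficients r/μ
    (mmol per gDW), so fixing biomass flux to any μ and minimizing uptake
    returns r(μ) = (r_anchor/μ_anchor)·μ exactly — linear through the origin,
    matching the table rate map.
    """
    rm = RateMap.from_anchors(anchors)  # validates consistency; raises CalibrationError

    m = cobra.Model("gmpc_toy")
    mets = {}
    for mid, comp in [
        ("glc__D_e", "e"), ("no3_e", "e"), ("co2_e", "e"), ("photon_e", "e"),
        ("o2_e", "e"), ("glc__D_c", "c"), ("no3_c", "c"), ("co2_c", "c"),
        ("photon_c", "c"), ("o2_c", "c"),
    ]:
        met = cobra.Metabolite(mid, compartment=comp)
        mets[mid] = met
    m.add_metabolites(list(mets.values()))

    def rxn(rid, stoich, lb, ub):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        m.add_reactions([r])
        r.add_metabolites({mets[k]: v for k, v in stoich.items()})
        return r

    big = 1000.0
    # Exchanges: positive flux = export, negative = uptake.
    rxn("EX_glc__D_e", {"glc__D_e": -1}, -big, big)
    rxn("EX_no3_e", {"no3_e": -1}, -big, big)
    rxn("EX_co2_e", {"co2_e": -1}, -big, big)
    rxn("EX_photon_e", {"photon_e": -1}, -big, big)
    rxn("EX_o2_e", {"o2_e": -1}, -big, big)
    # Transport
    rxn("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0, big)
    rxn("NO3t", {"no3_e": -1, "no3_c": 1}, 0, big)
    rxn("CO2t", {"co2_e": -1, "co2_c": 1}, -big, big)
    rxn("PHOTONt", {"photon_e": -1, "photon_c": 1}, 0, big)
    rxn("O2t", {"o2_e": -1, "o2_c": 1}, -big, big)

    # Autotrophic biomass: nitrate + CO2 + photons -> biomass + O2.
    # Carbon content ~40 mmol C per gDW; 10 mol photon per mol C fixed.
    c_per_gdw = 40.0
    rxn(
        "BIOMASS_light",
        {
            "no3_c": -rm.n_coeff_light,
            "co2_c": -c_per_gdw,
            "photon_c": -10.0 * c_per_gdw,
            "o2_c": c_per_gdw,
        },
        0, big,
    )
    # Heterotrophic biomass: glucose + nitrate -> biomass + respired CO2.
    co2_out = 6.0 * rm.g_coeff_dark - c_per_gdw
    rxn(
        "BIOMASS_dark",
        {
            "glc__D_c": -rm.g_coeff_dark,
            "no3_c": -rm.n_coeff_dark,
            "co2_c": co2_out,
            "o2_c": -co2_out,
        },
        0, big,
    )

    return StoichModel(
        model=m,
        biomass={GrowthMode.LIGHT: "BIOMASS_light", GrowthMode.DARK: "BIOMASS_dark"},
    )


_PACKAGED_TOY = Path(__file__).parent / "data" / "toy_model.json"


def toy_model() -> StoichModel:
    """Load the packaged toy-model fixture (falls back to rebuilding it)."""
    if _PACKAGED_TOY.exists():
        return load_model(_PACKAGED_TOY)
    return calibrate_toy_model()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_model(
    path: str | Path,
    dialect: str = "cobra-json",
    *,
    biomass_ids: Mapping[GrowthMode, str] | None = None,
    exchange_ids: Mapping[str, str] | None = None,
) -> StoichModel:
    """Read a stoichiometric model from COBRA JSON or SBML (Level-3 fbc).

    Designated reactions are resolved from explicit id maps; the defaults
    match the packaged toy fixture.
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file not found: {path}")
    try:
        if dialect == "cobra-json":
            model = load_json_model(str(path))
        elif dialect == "sbml":
            model = read_sbml_model(str(path))
        else:
            raise ModelFormatError(f"unknown dialect '{dialect}'")
    except ModelFormatError:
        raise
    except Exception as exc:  # parse failures from cobra/libsbml
        raise ModelFormatError(f"could not parse {path} as {dialect}: {exc}") from exc

    biomass = dict(biomass_ids) if biomass_ids else {
        GrowthMode.LIGHT: DEFAULT_IDS["biomass_light"],
        GrowthMode.DARK: DEFAULT_IDS["biomass_dark"],
    }
    exchanges = dict(exchange_ids) if exchange_ids else {
        "glucose": DEFAULT_IDS["glucose_exchange"],
        "nitrate": DEFAULT_IDS["nitrate_exchange"],
        "co2": DEFAULT_IDS["co2_exchange"],
        "photon": DEFAULT_IDS["photon_exchange"],
    }
    return StoichModel(model=model, biomass=biomass, exchanges=exchanges)


def save_model(sm: StoichModel, path: str | Path, dialect: str = "cobra-json") -> None:
    """Write the model back to COBRA JSON (default) or SBML."""
    path = Path(path)
    if dialect == "cobra-json":
        save_json_model(sm.model, str(path))
    elif dialect == "sbml":
        write_sbml_model(sm.model, str(path))
    else:
        raise ModelFormatError(f"unknown dialect '{dialect}'")


# ---------------------------------------------------------------------------
# FBA
# ---------------------------------------------------------------------------

def _max_feasible_mu(sm: StoichModel, mode: GrowthMode) -> float:
    with sm.model as m:
        for gm, rid in sm.biomass.items():
            rxn = m.reactions.get_by_id(rid)
            if gm is mode:
                rxn.bounds = (0.0, 1e6)
            else:
                rxn.bounds = (0.0, 0.0)
        m.objective = sm.biomass[mode]
        sol = _optimize_quietly(m)
        return float(sol.objective_value or 0.0)


def _optimize_quietly(model: cobra.Model):
    """Run optimize without cobra's infeasible-status warning; status is
    checked explicitly by the caller."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return model.optimize()


def solve_fba(
    sm: StoichModel,
    fixed_growth: float,
    minimize_order: Sequence[str] = ("glucose", "nitrate"),
    *,
    mode: GrowthMode = GrowthMode.DARK,
    photon_bound: float | None = None,
) -> FluxSolution:
    """FBA at a fixed growth rate with lexicographic minimal substrate uptake.

    The active mode's biomass flux is pinned to ``fixed_growth``; the other
    mode's biomass reaction is shut off.  Substrate uptakes are then
    minimized in ``minimize_order`` (carbon source first by convention),
    each stage fixing the previous stage's optimum within :data:`LP_TOL`.

    ``photon_bound`` caps photon uptake (mmol·gDW⁻¹·h⁻¹); used when the
    autotrophic model is evaluated inside a dark phase at minimal light.
    """
    if fixed_growth < 0:
        raise ValueError(f"growth rate must be >= 0, got {fixed_growth}")
    if mode not in sm.biomass:
        raise ModelConfigError(f"model has no biomass reaction for mode {mode}")

    with sm.model as m:
        for gm, rid in sm.biomass.items():
            rxn = m.reactions.get_by_id(rid)
            rxn.bounds = (fixed_growth, fixed_growth) if gm is mode else (0.0, 0.0)
        if photon_bound is not None:
            ex = m.reactions.get_by_id(sm.exchanges["photon"])
            ex.lower_bound = -abs(photon_bound)

        fluxes: dict[str, float] = {}
        solution = None
        for substrate in minimize_order:
            ex_id = sm.exchanges[substrate]
            # Uptake is negative exchange flux; minimizing uptake means
            # maximizing the exchange flux.
            m.objective = m.reactions.get_by_id(ex_id)
            m.objective_direction = "max"
            solution = _optimize_quietly(m)
            if solution.status != "optimal":
                raise InfeasibleGrowthError(fixed_growth, _max_feasible_mu(sm, mode))
            opt = float(solution.fluxes[ex_id])
            ex = m.reactions.get_by_id(ex_id)
            ex.bounds = (opt - LP_TOL, opt + LP_TOL)
        if solution is None:  # no substrates requested: plain feasibility solve
            m.objective = sm.biomass[mode]
            solution = _optimize_quietly(m)
            if solution.status != "optimal":
                raise InfeasibleGrowthError(fixed_growth, _max_feasible_mu(sm, mode))
        fluxes = {rid: float(v) for rid, v in solution.fluxes.items()}

    return FluxSolution(
        objective=fluxes[sm.biomass[mode]],
        fluxes=fluxes,
        status="optimal",
    )


def exchange_rates_at_mu(
    source: RateMap | StoichModel,
    mode: GrowthMode,
    mu: float,
    **fba_kwargs,
) -> tuple[float, float]:
    """Return ``(r_G, r_N)`` at growth rate ``mu``, from a table map or by FBA.

    Rates are uptake-positive mmol·gDW⁻¹·h⁻¹; r_G is 0 in LIGHT mode.
    """
    if mu < 0:
        raise ValueError(f"growth rate must be >= 0, got {mu}")
    if isinstance(source, RateMap):
        return source.rates(mode, mu)
    sol = solve_fba(source, mu, mode=mode, **fba_kwargs)
    r_g = sol.uptake(source.exchanges["glucose"])
    r_n = sol.uptake(source.exchanges["nitrate"])
    # Clean LP round-off on the zero side (including negative zero).
    return (r_g if r_g > 0.0 else 0.0), (r_n if r_n > 0.0 else 0.0)
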