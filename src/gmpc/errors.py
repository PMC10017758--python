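"""Exception hierarchy for gmpc."""


class GmpcError(Exception):
    """Base class for all gmpc errors."""


class ModelFormatError(GmpcError):
    """A model file could not be parsed under the requested dialect."""


class ModelConfigError(GmpcError):
    """A designated reaction (biomass or exchange) is missing or ambiguous."""


class CalibrationError(GmpcError):
    """Anchor rates are inconsistent or contradict the mode conventions."""


class InfeasibleGrowthError(GmpcError):
    """The requested growth rate is infeasible for the model's bounds."""

    def __init__(self, mu: float, max_mu: float):
        self.mu = mu
        self.max_mu = max_mu
        super().__init__(
            f"growth rate {mu:g} h^-1 is infeasible; maximum feasible "
            f"growth rate is {max_mu:g} h^-1"
        )


class FitError(GmpcError):
    """The dark-cycle parameter fit failed to converge."""


class IntegrationError(GmpcError):
    """The plant integrator failed (e.g. step-size collapse)."""


class ScenarioConfigError(GmpcError):
    """A scenario configuration is invalid or references unknown components."""
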