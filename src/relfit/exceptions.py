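"""Exception hierarchy shared across the package."""


class RelfitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RelfitError):
    """A problem, objective or optimiser specification is inconsistent."""


class InputError(RelfitError):
    """User-supplied data (files, tables, vectors) violates a precondition."""


class ModelDefinitionError(RelfitError):
    """The model lacks information needed for the requested operation
    (e.g. partial derivatives for sensitivity integration)."""


class IntegrationError(RelfitError):
    """The ODE solver failed (non-convergence or non-finite state).

    Carries the parameter vector and condition so the optimiser can map the
    failure to a penalty evaluation instead of crashing.
    """

    def __init__(self, message, theta=None, condition=None):
        super().__init__(message)
        self.theta = theta
        self.condition = condition


class NormalizationError(RelfitError):
    """A normalisation reference is missing, zero or negative.

    When raised for a *simulated* reference this signals an infeasible
    parameter set; objective code converts it into a large finite penalty.
    """

    def __init__(self, message, theta=None):
        super().__init__(message)
        self.theta = theta
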