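"""Exception hierarchy shared by all growdom modules."""


class GrowdomError(Exception):
    """Base class for all growdom-specific errors."""


class InvalidParameterError(GrowdomError, ValueError):
    """A model or solver parameter violates its precondition."""


class DistinctRatesRequiredError(GrowdomError):
    """The uncoupling transformation is singular for (near-)repeated rates.

    Callers should fall back to the repeated-rate closed forms or the
    per-mode matrix-exponential solver, which have no such restriction.
    """


class OutOfDomainError(GrowdomError, ValueError):
    """An evaluation point lies outside the moving domain [0, L(t)]."""


class NumericalIntegrationError(GrowdomError):
    """Adaptive quadrature failed to converge to the requested tolerance."""


class SolverFailureError(GrowdomError):
    """The finite-difference march produced non-finite values."""
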