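"""Exception hierarchy.

All package errors derive from :class:`Sc2FluxError` so callers can catch
one base class; validation failures name the violated constraint.
"""


class Sc2FluxError(Exception):
    """Base class for all package errors."""


class ValidationError(Sc2FluxError, ValueError):
    """An input object violates one of its declared invariants."""


class InsufficientDataError(Sc2FluxError, ValueError):
    """Too few data points for the requested estimator."""


class CarrierRequiredError(Sc2FluxError, ValueError):
    """A second-order (carrier-dependent) operation was requested on a
    carrier-free time course."""


class NoCrossingError(Sc2FluxError, ValueError):
    """A dose-response curve never crosses 50% viability and
    extrapolation was disallowed."""


class InsufficientRangeError(Sc2FluxError, ValueError):
    """Fewer than two viability points fall inside the declared
    linearity range."""


class ComparisonError(Sc2FluxError, ValueError):
    """Pharmacodynamic summaries for different compounds or incubation
    times cannot be compared."""


class InfeasibleBalanceError(Sc2FluxError, ValueError):
    """A mass balance would require a negative species concentration."""


class UndefinedQuotientError(Sc2FluxError, ZeroDivisionError):
    """An equilibrium quotient is 0/0 or otherwise undefined."""


class IndeterminateSumError(Sc2FluxError, ArithmeticError):
    """A free-energy sum contains both +inf and -inf terms."""


class SchemaError(Sc2FluxError, ValueError):
    """A CSV or config file does not match the expected schema."""
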