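"""Exception hierarchy shared by all pipeline stages."""


class ElectroablateError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(ElectroablateError, ValueError):
    """A configuration object violates its invariants (bad electrode layout,
    non-positive resistance, sites outside the dish, ...)."""


class ValidationError(ElectroablateError, ValueError):
    """Input data violate a stage's preconditions (missing replicates,
    midpoint outside the convex hull, empty mask, ...)."""


class DomainError(ElectroablateError, ValueError):
    """A scalar argument is outside the mathematical domain of an operation
    (negative charge, non-positive intensity ratio, p outside [0, 1])."""


class NumericsError(ElectroablateError, RuntimeError):
    """A numerical routine failed to converge or bracket a root."""
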