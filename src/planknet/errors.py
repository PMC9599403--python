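"""Exception hierarchy shared across the package."""


class PlanknetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PlanknetError, ValueError):
    """Input data violates a table contract (negative density, taxonomy gap, ...)."""


class ConfigurationError(PlanknetError, ValueError):
    """A configuration object or truth specification is inconsistent."""


class SizeError(PlanknetError, ValueError):
    """An input is too small for the requested computation."""


class EmptyIntersectionError(PlanknetError, ValueError):
    """The two zooplankton size fractions share no species."""


class UndefinedMetricError(PlanknetError, ArithmeticError):
    """A metric is undefined for this input (e.g. vulnerability when E = 0)."""
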