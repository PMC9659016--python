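"""Exception hierarchy shared across the package."""


class BerryoptError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BerryoptError, ValueError):
    """An argument violates a documented precondition."""


class NotDriedError(BerryoptError):
    """A moisture series never falls below the stopping threshold."""


class OutOfDomainError(BerryoptError, ValueError):
    """A network input lies outside the calibrated scaler domain."""


class UndefinedMetricError(BerryoptError, ValueError):
    """A fit metric is undefined for the given data (e.g. N <= k+1)."""


class DivergenceError(BerryoptError, RuntimeError):
    """Training produced a non-finite loss."""


class SchemaError(BerryoptError, ValueError):
    """A delimited-text file does not match the expected column schema."""
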