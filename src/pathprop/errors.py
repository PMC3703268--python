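"""Exception hierarchy shared across modules."""


class PathpropError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PathpropError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class SchemaError(PathpropError, ValueError):
    """An input table violates its required schema."""


class ConfigurationError(PathpropError, ValueError):
    """A configuration value is invalid or inconsistent."""


class NonConvergenceError(PathpropError, RuntimeError):
    """Iterative propagation failed to reach tolerance.

    Attributes
    ----------
    residual : float
        Max-norm change of the last iteration.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual
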