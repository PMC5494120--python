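"""Exception hierarchy shared across the package."""


class AdmorphError(Exception):
    """Base class for all package errors."""


class ValidationError(AdmorphError, ValueError):
    """Input violates a documented precondition or invariant."""


class ParseError(AdmorphError, ValueError):
    """A file could not be parsed; the message names the offending location."""


class ConfigurationError(AdmorphError, ValueError):
    """Invalid configuration: unknown keys, bad classifier spec, etc."""


class ConvergenceError(AdmorphError, RuntimeError):
    """An iterative solver failed to converge within its iteration budget."""

    def __init__(self, message: str, grad_norm: float | None = None):
        super().__init__(message)
        self.grad_norm = grad_norm
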