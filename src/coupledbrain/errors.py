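"""Exception hierarchy.

Everything raised on purpose derives from :class:`CoupledBrainError` so
callers (and the CLI) can catch one base class.
"""


class CoupledBrainError(Exception):
    """Base class for all package errors."""


class ConfigError(CoupledBrainError):
    """Invalid configuration; the message names the offending field."""


class ValidationError(CoupledBrainError):
    """Structurally invalid input data (tables, maps, labels)."""


class DegenerateInputError(CoupledBrainError):
    """Input is rank-deficient, constant, or otherwise leaves a statistic undefined."""


class ConvergenceError(CoupledBrainError):
    """An iterative fit failed to converge within its budget."""

    def __init__(self, message: str, *, max_iter: int | None = None, tol: float | None = None):
        super().__init__(message)
        self.max_iter = max_iter
        self.tol = tol
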