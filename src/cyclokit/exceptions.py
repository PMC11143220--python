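"""Exception hierarchy.

Validation errors (bad user input / malformed files) are distinguished from
computation errors (a well-posed calculation that cannot complete) so the CLI
can map them to distinct exit codes.
"""


class CycloKitError(Exception):
    """Base class for all package errors."""


class ValidationError(CycloKitError, ValueError):
    """Input violates a documented precondition."""


class ParseError(ValidationError):
    """A text file does not conform to its declared format."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class StructureError(ValidationError):
    """File parsed but is internally inconsistent (e.g. varying atom counts)."""


class FormatOverflowError(ValidationError):
    """A value cannot be represented in the fixed-width output columns."""


class ComputationError(CycloKitError, RuntimeError):
    """A well-formed computation failed to produce a result."""


class CapacityError(ComputationError):
    """Stochastic placement exhausted its retry budget."""


class ConvergenceError(ComputationError):
    """An iterative estimator failed to converge."""
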