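"""Exception hierarchy shared across the pipeline.

Every error a pipeline stage can raise maps to one of these, so the CLI can
translate failures into stable exit codes.
"""


class RppgBpError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(RppgBpError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(RppgBpError):
    """Input is structurally valid but numerically degenerate
    (rank-deficient covariance, collapsed simplex, ...)."""


class InsufficientDataError(RppgBpError):
    """Fewer valid observations than the operation requires."""

    def __init__(self, msg: str, n_valid: int | None = None, n_required: int | None = None):
        super().__init__(msg)
        self.n_valid = n_valid
        self.n_required = n_required


class OutOfRangeError(RppgBpError):
    """A query value falls outside the covered domain (e.g. BMI outside
    the parameter table's intervals)."""


class SchemaError(RppgBpError):
    """A file is readable but does not match the documented CSV/JSON schema."""


class UnderdeterminedError(RppgBpError):
    """A fit was requested with fewer records than free parameters."""
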