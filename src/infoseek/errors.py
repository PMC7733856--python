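"""Exception types shared across the package."""


class InfoseekError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(InfoseekError, ValueError):
    """An argument violates a documented precondition."""


class CalibrationError(InfoseekError, RuntimeError):
    """The adaptive staircase cannot reach the target accuracy for an observer."""


class SchemaError(InfoseekError, ValueError):
    """A table does not conform to the documented CSV schema."""


class CollinearityError(InfoseekError, ValueError):
    """A regression design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; offending columns: {self.columns}")


class InternalConsistencyError(InfoseekError, RuntimeError):
    """Generated output violates an internal invariant (e.g. NaN values)."""
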