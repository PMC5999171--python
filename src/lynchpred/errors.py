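"""Exception hierarchy shared across the package."""


class LynchpredError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LynchpredError):
    """A cohort file does not match the documented column schema."""


class RowError(LynchpredError):
    """A single cohort row failed parsing or validation.

    Carries the offending row id and a machine-readable reason so callers
    can log or surface the exact invariant that was violated.
    """

    def __init__(self, row_id: str, reason: str):
        self.row_id = row_id
        self.reason = reason
        super().__init__(f"row {row_id!r}: {reason}")


class ValidationError(LynchpredError):
    """A domain object violates one of its invariants."""


class EncodingError(LynchpredError):
    """A required covariate could not be encoded for a patient."""


class NotApplicableError(LynchpredError):
    """A model or rule does not apply to this patient (e.g. no CRC)."""


class FitError(LynchpredError):
    """Maximum-likelihood fitting failed (separation, divergence, ...)."""
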