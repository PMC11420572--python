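"""Exception hierarchy for engagekit."""


class EngageKitError(Exception):
    """Base class for all engagekit errors."""


class ValidationError(EngageKitError):
    """Input data violates a structural contract (bad menu label, negative day...)."""


class ParseError(EngageKitError):
    """A usage-log file could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class InvalidWindowError(EngageKitError):
    """A study window is degenerate (zero weeks) for the requested index."""


class InsufficientDataError(EngageKitError):
    """A series is too short for the requested ordinal-pattern analysis."""


class DegenerateSplitError(EngageKitError):
    """A group split (e.g. median dichotomization) produced an empty group."""


class DesignError(EngageKitError):
    """A model design matrix is rank deficient or otherwise unusable."""
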