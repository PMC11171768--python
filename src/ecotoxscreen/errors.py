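"""Exception hierarchy shared by the assay modules."""


class EcotoxError(ValueError):
    """Base class for all domain errors raised by this package."""


class InvalidInputError(EcotoxError):
    """An input value violates a precondition (e.g. zero seed count)."""


class InvalidControlError(EcotoxError):
    """A control/reference quantity is degenerate (zero or inverted)."""


class UndefinedMeasureError(EcotoxError):
    """A quantity has no defined value (e.g. mean length of no seedlings).

    Distinct from a value of zero: zero seedlings germinating gives G = 0
    but an *undefined* mean root length, not a root length of 0 cm.
    """


class EmptyGroupError(EcotoxError):
    """No replicates remain in a group after exclusion rules."""


class MustCorrectFirstError(EcotoxError):
    """A 0% or 100% rate reached the probit transform uncorrected."""


class NoLC50Error(EcotoxError):
    """The fitted dose-response line cannot be solved for a positive LC50."""


class DataValidationError(EcotoxError):
    """A data file or record set failed row-level validation."""

    def __init__(self, message: str, rows: list[str] | None = None):
        self.rows = rows or []
        if self.rows:
            message = message + "\n" + "\n".join(self.rows)
        super().__init__(message)


class ExtrapolationWarning(UserWarning):
    """An inverted response level lies outside the fitted dose range."""


class NonMonotoneResponseWarning(UserWarning):
    """A fitted dose-response slope has an unexpected sign."""
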