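"""Exception hierarchy shared across the package."""


class StandingError(Exception):
    """Base class for all package errors."""


class ValidationError(StandingError):
    """An input record or parameter violates its invariants.

    Carries an optional ``field`` naming the offending attribute and an
    optional ``row`` index for file-level diagnostics.
    """

    def __init__(self, message: str, *, field: str | None = None, row: int | None = None):
        self.field = field
        self.row = row
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


class HitRequiredError(StandingError):
    """Head-impulse test missing where the algorithm needs it.

    Raised when a patient sits in the unidirectional spontaneous-nystagmus
    branch but the HIT was not performed and the classifier is configured
    to treat that as an error (the default policy).
    """


class UndefinedMetricError(StandingError):
    """A diagnostic metric has a zero denominator and is undefined."""


class UndefinedKappaError(StandingError):
    """Chance agreement is 1 (all ratings in one category); kappa undefined."""


class SeparationError(StandingError):
    """Logistic fit hit complete or quasi-complete separation."""


class FormatError(StandingError):
    """A cohort file is structurally malformed (missing header, bad dialect)."""
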