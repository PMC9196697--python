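"""Exception hierarchy shared across the package.

Every parse/normalization failure is a distinct subclass so callers (and the
CLI) can branch on the failure category rather than on message text.
"""


class CohortCraftError(Exception):
    """Base class for all package errors."""


class ParseError(CohortCraftError, ValueError):
    """A free-text fragment could not be parsed into a structured form."""


class NumberParseError(ParseError):
    """A token expected to be a number (digit, word or Roman form) is not."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"unrecognized number token: {token!r}")


class NotAValueError(ParseError):
    """A span classified as a value entity contains no number."""


class MalformedRangeError(ParseError):
    """A numeric range whose lower bound exceeds its upper bound."""


class UnitError(ParseError):
    """A temporal quantity carries an unknown unit."""

    def __init__(self, unit: str):
        self.unit = unit
        super().__init__(f"unknown time unit: {unit!r}")


class DirectionMissingError(ParseError):
    """A temporal expression lacks a before/after reference-time word."""


class NoTimeSpanError(ParseError):
    """A temporal expression carries no usable duration (e.g. 'currently')."""


class DateLiteralError(ParseError):
    """A temporal expression is an absolute calendar date, which cannot be
    converted to an index-date-relative window without an anchor date."""


class TokenizationMismatchError(CohortCraftError):
    """An entity span maps to zero word tokens."""


class AnnotationConflictError(CohortCraftError):
    """A human annotation overlaps an existing human annotation."""


class NotFoundError(CohortCraftError, KeyError):
    """A criterion key or annotation id does not exist."""


class EmptyQueryError(CohortCraftError):
    """The representation contains no queryable, selected annotations."""


class SchemaMismatchError(CohortCraftError):
    """The target database is missing tables/columns of the OMOP-lite DDL."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(f"database schema mismatch; missing: {', '.join(missing)}")


class FixtureSpecError(CohortCraftError):
    """A planted-cohort description is inconsistent with the population size."""
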