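"""Exception hierarchy for cofrac.

All package errors derive from :class:`CofracError` so callers can catch
broadly; the subclasses distinguish file-format problems from semantic
validation failures.
"""


class CofracError(Exception):
    """Base class for all cofrac errors."""


class FormatError(CofracError):
    """A file could not be parsed (missing columns, malformed rows)."""


class ValidationError(CofracError):
    """Parsed data violates a domain invariant (duplicate accession, bad MW)."""


class InsufficientDataError(CofracError):
    """Too few data points for the requested fit or statistic."""


class UnknownAccessionError(CofracError, KeyError):
    """An accession does not resolve to a known protein record."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class UndefinedQuotientError(CofracError, ValueError):
    """The abundance quotient is undefined (zero or negative emPAI)."""
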