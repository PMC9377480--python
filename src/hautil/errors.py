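"""Exception hierarchy for hautil.

All validation-style failures derive from :class:`ValidationError` (a
``ValueError``), so callers that only care about "bad input" can catch one
type; protocol misuse (answering a finished session, chaining before the
anchor exists) derives from :class:`SequencingError` (a ``RuntimeError``).
"""


class HautilError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HautilError, ValueError):
    """An input violates a documented precondition or range."""


class FormatError(ValidationError):
    """A file does not conform to its declared format."""


class CalibrationError(ValidationError):
    """Moment-matching targets are infeasible for the requested family."""


class DomainError(ValidationError):
    """A lookup falls outside the supported domain (e.g. life-table ages)."""


class SequencingError(HautilError, RuntimeError):
    """An operation was invoked out of order in a stateful protocol."""


class ProtocolError(HautilError, RuntimeError):
    """A respondent or driver broke the question/answer protocol."""
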