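"""Exception hierarchy for readaudit.

All package-specific failures derive from :class:`ReadAuditError` so callers
(and the CLI) can catch one base class.
"""


class ReadAuditError(Exception):
    """Base class for all readaudit errors."""


class FormatError(ReadAuditError):
    """A file does not conform to its declared format."""


class MalformedRecordError(FormatError):
    """A single record inside a file is internally inconsistent."""


class TruncatedFileError(FormatError):
    """A file ends in the middle of a record."""


class UnknownReferenceError(FormatError):
    """An alignment names a reference sequence absent from the header."""


class ConsistencyError(ReadAuditError):
    """Derived quantities disagree with their inputs (upstream bug or bad data)."""


class UndefinedRateError(ReadAuditError):
    """A ratio was requested with a zero denominator."""
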