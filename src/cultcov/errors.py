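"""Exception hierarchy for the toolkit.

All errors raised while parsing external files derive from
:class:`FormatError` so callers can catch one type at the pipeline
boundary while unit tests can assert on the specific failure.
"""


class CultcovError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CultcovError):
    """A file does not conform to its declared format.

    Where possible the message names the offending line number or record.
    """


class DuplicateIdError(FormatError):
    """Two records in one file share an identifier."""


class CrossReferenceError(FormatError):
    """An identifier in one file does not resolve in its companion file."""


class MissingFileError(CultcovError):
    """A file referenced by a manifest does not exist."""


class PreconditionError(CultcovError):
    """An operation was called with arguments that violate its contract."""
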