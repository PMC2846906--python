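"""Exception hierarchy.

All user-facing errors derive from :class:`MomentPLSError` so callers (and
the CLI) can catch one base class.  ``ValueError`` is kept as a secondary
base so the package plays well with generic numeric code.
"""


class MomentPLSError(ValueError):
    """Base class for all errors raised by this package."""


class InputFormatError(MomentPLSError):
    """A delimited input file could not be parsed (names file and line)."""


class LabelError(MomentPLSError):
    """A sample is missing from the label table or carries an invalid label."""


class UsageError(MomentPLSError):
    """An operation was called with arguments violating its contract."""


class EmptyOutputError(MomentPLSError):
    """A filtering step removed every row; carries a diagnostic message."""
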