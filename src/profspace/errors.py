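"""Exception hierarchy.

All package errors derive from :class:`ProfspaceError` so callers can catch
one base class; the subclasses distinguish malformed files from invalid
values/inputs.
"""


class ProfspaceError(Exception):
    """Base class for all profspace errors."""


class FormatError(ProfspaceError):
    """A file or structure violates the expected format (duplicates, bad header...)."""


class ParseError(FormatError):
    """A cell or token could not be parsed; message carries coordinates."""


class ValidationError(ProfspaceError, ValueError):
    """A value or combination of values violates an invariant."""
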