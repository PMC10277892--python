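"""Exception hierarchy.

All package-specific failures derive from :class:`StrindexError` so callers
can catch one base class; parameter/validation errors also derive from
``ValueError`` for idiomatic use.
"""


class StrindexError(Exception):
    """Base class for all strindex errors."""


class InvalidParameterError(StrindexError, ValueError):
    """A parameter violates its documented constraints."""


class ValidationError(StrindexError, ValueError):
    """Input data violates a structural invariant (ordering, emptiness, mismatch)."""


class FormatError(StrindexError):
    """A file could not be parsed in the requested dialect."""


class CalibrationError(StrindexError):
    """Size calibration is impossible with the given ladder."""


class ConfigError(StrindexError):
    """A run configuration file is missing or invalid."""
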