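"""Exception hierarchy.

All user-facing validation failures derive from :class:`LordistError` so the
CLI can map them to a single exit code.
"""


class LordistError(ValueError):
    """Base class for all validation and configuration errors."""


class FormatError(LordistError):
    """A file does not have the expected layout (missing column, bad cell)."""


class DuplicateKeyError(LordistError):
    """A (subject, feature, time) key occurs more than once."""


class ValidationError(LordistError):
    """Values violate an invariant (negative, non-finite, out of range)."""


class JoinError(LordistError):
    """Sample IDs in a matrix cannot be matched to the metadata table."""


class ConfigurationError(LordistError):
    """An impossible parameter combination was requested."""


class InsufficientDataError(LordistError):
    """Too few observations/subjects for the requested operation."""


class RankError(LordistError):
    """The smoothing system is singular; a positive penalty is required."""
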