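"""Exception hierarchy for dmrkit.

All dmrkit-specific failures derive from :class:`DmrkitError` so callers can
catch pipeline problems without masking programming errors.
"""


class DmrkitError(Exception):
    """Base class for all dmrkit errors."""


class ParseError(DmrkitError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(DmrkitError):
    """A structurally valid file violates a format contract (e.g. end <= start)."""


class ConsistencyError(DmrkitError):
    """Inputs disagree with each other (e.g. conflicting contexts at a position)."""


class ValidationError(DmrkitError):
    """An argument or configuration value violates a precondition."""


class ConfigurationError(DmrkitError):
    """A run configuration or manifest is incomplete or self-contradictory."""


class UndefinedValueError(DmrkitError):
    """A requested quantity is undefined (e.g. methylation level at zero coverage)."""


class GenerationError(DmrkitError):
    """The synthetic-data generator could not satisfy a placement request."""
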