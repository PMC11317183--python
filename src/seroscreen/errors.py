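"""Exception hierarchy used across the package."""


class SeroscreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SeroscreenError):
    """A file does not conform to the expected dialect (bad header, missing column)."""


class ValidationError(SeroscreenError):
    """Parsed content violates a structural invariant (bad coordinate, duplicate id)."""


class ConfigurationError(SeroscreenError):
    """An operation was invoked with an inconsistent or incomplete configuration."""


class InsufficientDataError(SeroscreenError):
    """Too few observations to compute the requested statistic."""


class MissingChannelError(SeroscreenError):
    """A spot record does not carry the requested fluorescence channel."""
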