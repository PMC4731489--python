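"""Exception hierarchy shared across the package."""


class MultiERPError(Exception):
    """Base class for all package errors."""


class ConfigError(MultiERPError):
    """Invalid paradigm configuration."""


class GenerationError(MultiERPError):
    """Schedule generation could not honor its constraints."""


class RuleError(MultiERPError):
    """Response rule queried for a trial it does not apply to."""


class DomainError(MultiERPError):
    """Input outside the documented domain of an operation."""


class EncodingError(MultiERPError):
    """Event-marker encoding of an unresolved or malformed trial."""


class ParameterError(MultiERPError):
    """Invalid numeric/structural parameter to a processing operation."""


class SelectionError(MultiERPError):
    """An epoch/event selection matched nothing (or lost a required cell)."""


class EqualizationError(MultiERPError):
    """Luminance equalization cannot reach the requested tolerance."""
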