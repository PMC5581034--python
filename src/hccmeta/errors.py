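"""Exception hierarchy for the meta-analysis pipeline.

All errors derive from :class:`HccMetaError` so callers (and the CLI) can
distinguish user-input problems from genuine bugs with one ``except``.
"""


class HccMetaError(Exception):
    """Base class for all package errors."""


class ParseError(HccMetaError, ValueError):
    """A study/contingency/KM file could not be parsed; names the line."""


class ValidationError(HccMetaError, ValueError):
    """A record violates a domain invariant; names the study and field."""


class DomainError(HccMetaError, ValueError):
    """An operation received inputs outside its mathematical domain."""


class EmptyInputError(HccMetaError, ValueError):
    """An operation requiring data received an empty collection."""


class EffectLookupError(HccMetaError, LookupError):
    """No effect source matches the requested outcome."""


class RuleError(HccMetaError, ValueError):
    """A subgroup rule references an unknown study field."""


class ConfigError(HccMetaError, ValueError):
    """A simulation or pipeline configuration is invalid or incomplete."""
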