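"""Exception hierarchy shared across the package."""


class NbsmaError(Exception):
    """Base class for all package errors."""


class ConfigError(NbsmaError):
    """Invalid configuration (unknown marker, bad probability, ...)."""


class ParseError(NbsmaError):
    """Malformed cohort or panel file."""


class InsufficientDataError(NbsmaError):
    """Too few observations for the requested statistic."""


class UndefinedEffectError(NbsmaError):
    """Effect size undefined (zero pooled variance)."""


class DegenerateInputError(NbsmaError):
    """Input is structurally degenerate for the requested analysis."""
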