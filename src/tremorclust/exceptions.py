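"""Exception hierarchy for tremorclust."""


class TremorClustError(Exception):
    """Base class for all tremorclust errors."""


class ParseError(TremorClustError):
    """A CSV input could not be parsed or failed validation."""


class EmptyInstanceError(TremorClustError):
    """No rest-period samples could be extracted for a recording instance.

    Instances with no usable rest annotation must be excluded from the
    analysis rather than silently contributing an empty modulus series.
    """


class ConfigurationError(TremorClustError):
    """A task or simulation configuration is internally inconsistent."""
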