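"""Exception hierarchy shared by all pipeline stages."""


class LyricTraceError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LyricTraceError):
    """A configuration value is outside its valid range or inconsistent."""


class DataIntegrityError(LyricTraceError):
    """Input records contradict each other (e.g. a matched keyword missing
    from the lexicon, or a timestamp outside the configured date range)."""


class FormatError(LyricTraceError):
    """An external file does not parse as its declared format."""


class InsufficientDataError(LyricTraceError):
    """Too few observations for the requested operation."""


class SingularFitError(LyricTraceError):
    """Least-squares fit is undefined (all time indices identical)."""


class UndefinedInputError(LyricTraceError):
    """An operation received an input it is mathematically undefined for
    (e.g. aligning an empty token sequence)."""
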