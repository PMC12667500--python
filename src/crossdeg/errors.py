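"""Exception hierarchy shared across the pipeline."""


class CrossDEGError(Exception):
    """Base class for all package errors."""


class ValidationError(CrossDEGError, ValueError):
    """Malformed or inconsistent input data; the message names the location."""


class ParseError(ValidationError):
    """A file that does not conform to its dialect."""


class ConfigError(CrossDEGError, ValueError):
    """Invalid configuration; the message names the offending field(s)."""


class DegenerateInputError(CrossDEGError, ValueError):
    """Structurally valid input on which the requested statistic is undefined."""
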