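"""Exception hierarchy shared across the package."""


class StressmetaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StressmetaError):
    """A configuration value is invalid; the message names the field."""


class ParseError(StressmetaError):
    """An input file violates its documented dialect.

    Where possible the message carries the offending line number or
    identifier so the file can be fixed by hand.
    """


class ContrastError(StressmetaError):
    """A contrast cannot be evaluated on the given dataset."""
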