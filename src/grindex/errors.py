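"""Exception hierarchy shared across the package."""


class GrindexError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GrindexError):
    """A dialect, config file, or generative setup is malformed."""


class ValidationError(GrindexError):
    """A record or value violates its domain contract."""


class DegenerateDataError(GrindexError):
    """A statistical routine received input on which it is undefined
    (e.g. all pooled values identical, or a constant correlate)."""
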