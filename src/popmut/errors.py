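"""Exception hierarchy shared across the package."""


class PopmutError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PopmutError):
    """A file could not be parsed as the format its reader expects."""


class ParameterError(PopmutError, ValueError):
    """A function was called with invalid or inconsistent parameters."""


class MissingDataError(PopmutError):
    """An operation that requires complete genotypes met missing calls."""
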