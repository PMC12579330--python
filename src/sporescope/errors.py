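"""Exception types shared across the toolkit."""


class SporescopeError(Exception):
    """Base class for all sporescope errors."""


class ValidationError(SporescopeError, ValueError):
    """Raised when inputs violate a documented precondition or invariant."""


class InputFormatError(SporescopeError, IOError):
    """Raised when a file cannot be read or parsed."""
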