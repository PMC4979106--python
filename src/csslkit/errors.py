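"""Exception hierarchy shared across the package."""


class CsslkitError(Exception):
    """Base class for all csslkit errors."""


class ValidationError(CsslkitError):
    """Raised when an input file or in-memory object violates its contract."""
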