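"""Exception hierarchy shared across the package."""


class SymarchError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SymarchError):
    """A file or field does not conform to the expected text format."""


class CoordinateError(SymarchError):
    """A genomic coordinate violates an invariant (bounds, ordering, overlap)."""


class UnresolvedReferenceError(SymarchError):
    """An identifier points at an object that does not exist."""


class ConfigError(SymarchError):
    """A configuration value is missing, inconsistent, or out of range."""
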