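"""Exception types shared across the package."""


class MethEnrichError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethEnrichError, ValueError):
    """An input file does not conform to its declared format."""


class ValidationError(MethEnrichError, ValueError):
    """Structurally well-formed input violates a semantic invariant."""
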