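"""Exception hierarchy for lungembed."""


class LungembedError(Exception):
    """Base class for all lungembed errors."""


class FormatError(LungembedError):
    """Unsupported, unreadable or malformed input file/series."""


class GeometryError(LungembedError):
    """Inconsistent or mismatched volume geometry (dims, spacing, positions)."""


class ParameterError(LungembedError, ValueError):
    """Invalid parameter value."""


class PhantomSpecError(LungembedError):
    """Phantom specification violates a geometric invariant."""


class PhantomValidationError(LungembedError):
    """Phantom generation-time self-validation failed (truth != oracle)."""
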