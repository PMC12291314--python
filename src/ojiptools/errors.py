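"""Exception hierarchy shared across the package."""


class OJIPError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OJIPError):
    """An input file does not match the declared dialect (e.g. missing column)."""


class ValidationError(OJIPError):
    """Data violates a structural invariant (non-monotone times, bad labels...)."""


class ExtractionError(OJIPError):
    """A landmark's nominal time lies outside the trace support."""


class DegenerateTransientError(OJIPError):
    """The transient carries no usable rise (flat or decreasing trace)."""


class SingularParameterError(OJIPError):
    """A derived quantity hits a pole (e.g. VJ = 1, phiPo = 0)."""

    def __init__(self, quantity: str, message: str | None = None):
        self.quantity = quantity
        super().__init__(message or f"singular value for {quantity!r}")


class NormalizationError(OJIPError):
    """A band cannot be normalized (reference landmark <= F0)."""


class UsageError(OJIPError):
    """An operation was called with structurally unusable inputs."""
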