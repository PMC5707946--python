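"""Exception hierarchy for grey-model input validation."""


class GreycastError(Exception):
    """Base class for all greycast errors."""


class NonNegativityViolation(GreycastError):
    """A series contains a negative observation; GM(1,1) requires non-negative input."""


class TooShort(GreycastError):
    """A series has fewer than the minimum number of observations (4)."""


class ZeroObservation(GreycastError):
    """A relative-error computation hit a zero observation."""


class LengthMismatch(GreycastError):
    """Two paired sequences have different lengths."""


class HorizonNonPositive(GreycastError):
    """A forecast horizon must be a positive integer."""


class SingularDesign(GreycastError):
    """The least-squares design is degenerate (fewer than 2 usable rows)."""


class NonPositiveGenerated(GreycastError):
    """A synthetic generator produced non-positive values."""
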