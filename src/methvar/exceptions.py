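"""Exception hierarchy for methvar."""


class MethvarError(Exception):
    """Base class for all methvar errors."""


class ValidationError(MethvarError, ValueError):
    """Raised when an input table or argument fails validation."""


class NonEstimableRegionError(MethvarError):
    """Raised when a region's design is singular and no fit exists."""


class DegenerateRegionError(MethvarError):
    """Raised when a region carries no residual variation (all residuals zero)."""
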