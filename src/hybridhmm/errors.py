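"""Exception types shared across the package."""


class HybridHMMError(Exception):
    """Base class for package errors."""


class FormatError(HybridHMMError, ValueError):
    """A delimited-text input could not be parsed (carries line numbers)."""


class ValidationError(HybridHMMError, ValueError):
    """Input violates a structural invariant (overlaps, unknown ids, ...)."""


class ShapeError(HybridHMMError, ValueError):
    """Array dimensions of paired containers disagree."""


class EstimationError(HybridHMMError, ValueError):
    """A model parameter cannot be estimated from the given data."""


class CalibrationError(HybridHMMError, ValueError):
    """Platt sigmoid calibration received degenerate data."""
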