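"""Exception types shared across the package."""


class CellWaterError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(CellWaterError):
    """A multi-exponential model violates its structural invariants."""


class EmptyCurveError(CellWaterError):
    """A decay curve has no usable samples for the requested operation."""


class FitError(CellWaterError):
    """Nonlinear least squares failed to converge on any start.

    Carries the best partial result found, if any, in ``best_so_far``.
    """

    def __init__(self, message, best_so_far=None):
        super().__init__(message)
        self.best_so_far = best_so_far


class UnsupportedModelError(CellWaterError):
    """Compartment assignment requested for a model order it does not support."""


class InsufficientDataError(CellWaterError):
    """Too few accepted measurements to build or analyse a series."""


class DegenerateHistogramError(CellWaterError):
    """Image histogram has fewer than two occupied grey levels."""


class ParseError(CellWaterError):
    """A delimited-text input failed validation; message names the line."""
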