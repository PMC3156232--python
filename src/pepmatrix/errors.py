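"""Exception hierarchy shared across pepmatrix modules."""


class PepmatrixError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(PepmatrixError, ValueError):
    """Sequence contains a character outside the 20 standard one-letter codes."""


class PHRangeError(PepmatrixError, ValueError):
    """pH outside the physical [0, 14] range."""


class UndefinedPIError(PepmatrixError, ValueError):
    """Isoelectric point requested for a sequence with no ionizable groups."""


class DesignError(PepmatrixError, ValueError):
    """Residue ladder or matrix construction violates a design invariant."""


class MeasurementError(PepmatrixError, ValueError):
    """Physically invalid raw measurement (e.g. non-positive initial absorbance)."""


class AssayDesignError(PepmatrixError, ValueError):
    """Samples in one isotherm disagree on cell count, diameter, or volume."""


class DataError(PepmatrixError, ValueError):
    """Not enough (or degenerate) data for the requested fit."""


class FitError(PepmatrixError, RuntimeError):
    """Nonlinear fit failed to converge; carries the initializer values."""

    def __init__(self, message, init=None):
        super().__init__(message)
        self.init = init


class QuantitationError(PepmatrixError, ValueError):
    """Invalid fluorescence quantitation input (e.g. non-positive background)."""


class ProfileError(PepmatrixError, ValueError):
    """Binding-profile assembly or comparison problem (missing cells, shape mismatch)."""


class PlanError(PepmatrixError, ValueError):
    """Pool plan cannot be constructed (indivisible sizes, wrong counts)."""


class ConsistencyError(PepmatrixError, ValueError):
    """Pooled-screen calls are mutually contradictory."""


class FormatError(PepmatrixError, ValueError):
    """Malformed library FASTA or assay/intensity CSV."""
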