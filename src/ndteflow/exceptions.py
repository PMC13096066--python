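"""Exception hierarchy shared across the pipeline."""


class NDTEFlowError(Exception):
    """Base class for all package errors."""


class ValidationError(NDTEFlowError, ValueError):
    """Invalid argument or malformed input."""


class StationarityError(NDTEFlowError):
    """A vector-autoregressive coefficient set is non-stationary.

    Carries the offending companion-matrix spectral radius.
    """

    def __init__(self, spectral_radius: float, which: str = "base"):
        self.spectral_radius = float(spectral_radius)
        self.which = which
        super().__init__(
            f"VAR coefficients ({which}) are non-stationary: companion spectral "
            f"radius {spectral_radius:.4f} >= 1"
        )


class DegenerateInputError(NDTEFlowError):
    """Input carries no usable signal (e.g. constant trace, no candidates)."""
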