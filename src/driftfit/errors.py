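"""Exception types shared across the package."""


class DriftfitError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DriftfitError, ValueError):
    """A diffusion parameter is outside its admissible domain."""


class DesignError(DriftfitError, RuntimeError):
    """Constrained session-design generation failed within its retry budget."""


class DatasetFormatError(DriftfitError, ValueError):
    """A trial table on disk violates the expected schema."""


class FitError(DriftfitError, RuntimeError):
    """Maximum-likelihood fitting failed for every start."""


class DegenerateDataError(DriftfitError, ValueError):
    """Input data are degenerate for the requested statistic (e.g. constant)."""
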