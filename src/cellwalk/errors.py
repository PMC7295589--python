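"""Exception hierarchy shared across the pipeline stages."""


class CellwalkError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CellwalkError):
    """An input file does not have the expected layout (missing columns, bad header)."""


class DataError(CellwalkError):
    """The input parses but violates a data invariant (duplicates, unphysical values)."""


class InsufficientDataError(DataError):
    """Too few observations for the requested computation."""


class DegenerateDataError(DataError):
    """All observations identical (or otherwise degenerate) where spread is required."""


class ParameterError(CellwalkError):
    """A parameter is outside its documented range."""


class AlignmentError(DataError):
    """Tracks cannot be aligned on a common acquisition grid."""


class FitError(CellwalkError):
    """An optimisation failed to converge; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


class ConfigError(CellwalkError):
    """A run or simulation configuration is invalid."""
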