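"""Exception hierarchy shared across the package."""


class SorsmixError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SorsmixError, ValueError):
    """A precondition on an argument was violated."""


class NumericalError(SorsmixError, ArithmeticError):
    """A numerical procedure failed (ill-conditioned fit, degenerate data)."""


class GridMismatchError(SorsmixError, ValueError):
    """Two spectra live on different wavenumber grids; no silent resampling."""


class SpectralParseError(SorsmixError, ValueError):
    """A spectral CSV file could not be parsed; message names row/column."""
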