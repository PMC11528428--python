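"""Exception hierarchy shared by all pipeline stages."""


class SmlmeqError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SmlmeqError):
    """Invalid run configuration (missing column, bad dialect, bad flag)."""


class ParseError(SmlmeqError):
    """A file could not be parsed; message carries the offending row."""


class ParameterError(SmlmeqError, ValueError):
    """A function argument is outside its supported domain."""


class DataError(SmlmeqError):
    """Input data violate a precondition (empty table, too few points)."""


class DegenerateGeometryError(SmlmeqError):
    """Tessellation input is degenerate (collinear / cocircular points)."""


class ResolutionError(SmlmeqError):
    """Raster pixel too coarse for the requested kernel width."""


class UndefinedConstantError(SmlmeqError):
    """An equilibrium constant is undefined (zero free molecules or pairs)."""


class FitError(SmlmeqError):
    """Nonlinear fit failed; carries the initial guess and last residual."""

    def __init__(self, message, initial_guess=None, residual=None):
        super().__init__(message)
        self.initial_guess = initial_guess
        self.residual = residual
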