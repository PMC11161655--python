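"""Exception hierarchy used across the package."""


class CtrlredError(Exception):
    """Base class for all package errors."""


class ParameterError(CtrlredError, ValueError):
    """A parameter is outside its admissible range."""


class FormatError(CtrlredError, ValueError):
    """An input file or matrix violates the expected format."""


class ValidationError(CtrlredError, ValueError):
    """Input data fails a precondition."""


class DegenerateInputError(CtrlredError, ValueError):
    """Input is degenerate for the requested operation (e.g. all-zero matrix)."""


class ConfigurationError(CtrlredError, ValueError):
    """Inconsistent parcellation or run configuration."""


class DiagnosticsError(CtrlredError, ValueError):
    """A model diagnostic (e.g. collinearity) rules out a trustworthy fit."""


class DivergenceError(CtrlredError, ArithmeticError):
    """A series or transform does not converge for the given input."""


class DegenerateBreakpointWarning(UserWarning):
    """The fitted piecewise model is indistinguishable from a single line."""
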