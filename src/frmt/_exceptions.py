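"""Exception hierarchy shared by all frmt modules."""


class FrmtError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(FrmtError):
    """A required configuration item (e.g. label column) is missing or invalid."""


class ValidationError(FrmtError):
    """Input data violates a documented invariant (e.g. a class with < 2 samples)."""


class ParseError(FrmtError):
    """A cell in a delimited input file could not be parsed as a number."""


class ShapeError(FrmtError):
    """Vector/matrix dimensions are inconsistent."""


class ParameterError(FrmtError):
    """An operation received an out-of-range or unknown parameter."""


class ConsistencyError(FrmtError):
    """Multiple inputs that must agree (e.g. rankings over one feature set) do not."""


class EvaluationError(FrmtError):
    """A performance measure was asked for on degenerate input (e.g. one class)."""


class StratificationError(EvaluationError):
    """A cross-validation fold ended up with a single class."""


class CoverageError(FrmtError):
    """An evaluation grid is missing cells required by an analysis."""
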