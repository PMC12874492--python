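"""Exception hierarchy shared across the package."""


class MFSUnetError(Exception):
    """Base class for package errors."""


class InvalidParameterError(MFSUnetError, ValueError):
    """An argument violates an operation's precondition."""


class ConfigurationError(MFSUnetError, ValueError):
    """A configuration object is internally inconsistent."""


class NumericError(MFSUnetError, ArithmeticError):
    """Non-finite values where finite ones are required."""


class DegenerateStatisticError(MFSUnetError, ValueError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class LeakageError(MFSUnetError, RuntimeError):
    """Patient identifiers overlap between training and evaluation splits."""


class TrainingDivergedError(MFSUnetError, RuntimeError):
    """The training loss became non-finite."""
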