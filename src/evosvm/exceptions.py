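"""Exception hierarchy.

Every error the package raises deliberately derives from :class:`EvosvmError`,
so callers (and the CLI) can distinguish user/input problems from genuine
bugs.
"""


class EvosvmError(Exception):
    """Base class for all errors raised by evosvm."""


class InvalidArgumentError(EvosvmError, ValueError):
    """An argument violates a documented precondition."""


class InvalidInputError(EvosvmError, ValueError):
    """Input data (files, arrays, label tables) is malformed or inconsistent."""


class DegenerateSignalError(EvosvmError, ValueError):
    """A region's time series is constant, so Pearson r is undefined."""


class SplitInfeasibleError(EvosvmError, ValueError):
    """A requested train/validation/test split cannot satisfy its constraints."""


class DegenerateTrainingError(EvosvmError, RuntimeError):
    """A base classifier's training part contained a single class."""


class InvalidConfigError(EvosvmError, ValueError):
    """A run configuration is internally inconsistent or infeasible."""


class UndefinedMetricError(EvosvmError, ZeroDivisionError):
    """A ratio metric has an empty denominator; reported, never coerced to 0."""


class InvalidStateError(EvosvmError, RuntimeError):
    """An object is used before it holds the state the operation requires."""


class PersistenceError(EvosvmError, ValueError):
    """A serialized ensemble or history file is missing or incompatible."""
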