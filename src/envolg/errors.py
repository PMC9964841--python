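"""Exception hierarchy.

Each class maps to a distinct CLI exit code (see :mod:`envolg.cli`):
domain errors are bad numeric inputs, regime errors are parameter
combinations outside the model's admissible region (a violated
assumption), convergence errors come from iterative solvers, and
calibration errors from target-matching failures.
"""


class EnvolgError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DomainError(EnvolgError, ValueError):
    """An input violates a mathematical precondition (e.g. k <= 0)."""

    exit_code = 3


class InvalidRegimeError(EnvolgError):
    """Parameters leave the admissible region (a model assumption fails)."""

    exit_code = 4


class ConvergenceError(EnvolgError):
    """An iterative solver failed to converge within its budget."""

    exit_code = 5


class CalibrationError(EnvolgError):
    """A calibration target cannot be matched (e.g. root not bracketed)."""

    exit_code = 6
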