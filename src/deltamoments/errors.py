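"""Typed exceptions.

Statistics that are mathematically undefined on an input (zero variance,
|r| = 1) raise :class:`UndefinedStatisticError` or :class:`MomentDomainError`
rather than returning 0 or NaN, so pipelines can count and report exclusions.
"""


class DeltaMomentsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DeltaMomentsError, ValueError):
    """Input violates a precondition (too few observations, bad n, ...)."""


class UndefinedStatisticError(DeltaMomentsError, ArithmeticError):
    """The statistic is undefined on this sample (e.g. zero variance)."""


class MomentDomainError(DeltaMomentsError, ValueError):
    """Parameter outside the admissible domain (|r| >= 1, infeasible moments)."""


class ConvergenceError(DeltaMomentsError, RuntimeError):
    """An iterative procedure failed to converge within its bounds."""


class ConfigError(DeltaMomentsError, ValueError):
    """Malformed configuration (unknown key, bad grid, schema mismatch)."""
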