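"""Exception hierarchy for semconn.

All errors raised by the package derive from :class:`SemConnError` so callers
can catch one base class; the CLI maps input errors to exit code 2 and
numerical failures to exit code 3.
"""


class SemConnError(Exception):
    """Base class for all semconn errors."""


class DimensionError(SemConnError, ValueError):
    """Shapes or lengths of inputs are inconsistent."""


class DegenerateInputError(SemConnError, ValueError):
    """Input is degenerate (constant row, all-zero matrix, zero spectrum)."""


class DomainError(SemConnError, ValueError):
    """A scalar argument is outside its mathematical domain."""


class DefinitenessError(SemConnError, ValueError):
    """A matrix required to be positive definite is not."""


class SingularModelError(SemConnError, ValueError):
    """I - K is singular so the implied correlation does not exist."""


class LabelingError(SemConnError, ValueError):
    """Region labels of two models do not match."""


class ConfigError(SemConnError, ValueError):
    """An optimizer configuration value is invalid."""


class GenerationError(SemConnError, RuntimeError):
    """Synthetic-network generation failed to satisfy its constraints."""
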