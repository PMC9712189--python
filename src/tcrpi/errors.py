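"""Exception hierarchy for the tcrpi package.

All package errors derive from :class:`TcrpiError` so callers can catch the
package's failures with a single handler while still distinguishing
configuration mistakes from data problems.
"""


class TcrpiError(Exception):
    """Base class for all errors raised by tcrpi."""


class ConfigurationError(TcrpiError, ValueError):
    """A configuration object or parameter violates a stated constraint."""


class DomainError(TcrpiError, ValueError):
    """An input is outside the mathematical domain of an operation."""


class SchemaError(TcrpiError, ValueError):
    """A table, matrix or model is missing a required entity (gene, pair, column)."""


class DegenerateInputError(DomainError):
    """Input is formally valid but degenerate (e.g. a constant matrix)."""


class UndefinedTestError(DomainError):
    """A statistical test is undefined for the given data (e.g. zero events)."""


class ConvergenceError(TcrpiError, RuntimeError):
    """A numerical fit failed to converge."""
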