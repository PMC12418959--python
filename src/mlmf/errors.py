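"""Exception hierarchy for mlmf.

All errors derive from :class:`MLMFError` so callers can catch the package's
failures with a single ``except`` clause while still distinguishing parse,
validation, configuration and numerical problems.
"""


class MLMFError(Exception):
    """Base class for all mlmf errors."""


class ParseError(MLMFError, ValueError):
    """A file could not be parsed (malformed or non-numeric cell)."""


class ValidationError(MLMFError, ValueError):
    """An input violates a structural invariant (duplicates, shapes, coverage)."""


class AlignmentError(MLMFError, ValueError):
    """A view refers to samples absent from the intact sample set."""


class ConfigurationError(MLMFError, ValueError):
    """A solver or simulation configuration is inconsistent with the data."""


class NumericalError(MLMFError, ArithmeticError):
    """A solver produced non-finite values; carries context about where."""


class SingularityError(MLMFError, ArithmeticError):
    """The consensus system is singular (some sample observed in zero views)."""
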