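"""Exception hierarchy for binscm.

All library errors derive from :class:`BinscmError` so callers (notably the
CLI) can catch one type and turn it into a diagnostic exit.
"""


class BinscmError(Exception):
    """Base class for all binscm errors."""


class BinaryFormatError(BinscmError, ValueError):
    """A file or matrix is not a valid binary dataset (non-{0,1} cell,
    duplicate or empty column names, empty body, missing values)."""


class DegenerateColumnError(BinscmError, ValueError):
    """An operation requires a column that takes both values 0 and 1."""


class UndefinedConditionalError(BinscmError, ZeroDivisionError):
    """A conditional probability was requested for a conditioning event with
    zero support.  Distinct from a probability whose value is 0."""


class UnstableStatisticError(BinscmError, RuntimeError):
    """More than half of the bootstrap replicates could not evaluate a
    statistic, so its sampling distribution is not trustworthy."""
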