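"""Exception hierarchy shared across the toolkit.

CLI exit-code mapping: :class:`UsageError` -> 2, :class:`DataError` -> 3,
:class:`NumericalError` -> 4.
"""


class MatrixBankError(Exception):
    """Base class for all toolkit errors."""


class UsageError(MatrixBankError):
    """Invalid invocation or argument (CLI exit code 2)."""


class ConfigurationError(MatrixBankError):
    """Inconsistent or infeasible configuration supplied by the caller."""


class DataError(MatrixBankError):
    """Malformed input data (CLI exit code 3)."""


class ParseError(DataError):
    """File failed parsing or schema validation.

    ``location`` carries a JSON-pointer-like path (or row/column reference)
    identifying the offending element.
    """

    def __init__(self, message: str, location: str | None = None):
        self.location = location
        super().__init__(f"{location}: {message}" if location else message)


class NumericalError(MatrixBankError):
    """Numerical failure during estimation (CLI exit code 4)."""


class RuleViolationError(MatrixBankError):
    """Cell contents are inconsistent with the rule being applied."""


class GenerationError(MatrixBankError):
    """Item composition exhausted its retry budget."""


class DegenerateItemError(NumericalError):
    """An item has no maximum-likelihood estimate (all-correct/all-wrong)."""


class CollinearityError(NumericalError):
    """Regression design matrix is rank deficient."""

    def __init__(self, message: str, columns: list[str] | None = None):
        self.columns = columns or []
        super().__init__(message)


class UndefinedStatisticError(NumericalError):
    """A statistic (e.g. a correlation on a constant vector) is undefined."""
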