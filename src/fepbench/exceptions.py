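"""Exception hierarchy for fepbench."""


class BenchmarkError(Exception):
    """Base class for all fepbench errors."""


class SchemaError(BenchmarkError):
    """A required column is missing or misnamed in an input table."""


class DuplicateKeyError(BenchmarkError):
    """The same (TKI, mutation) key appears more than once."""

    def __init__(self, keys):
        self.keys = list(keys)
        super().__init__(f"duplicate (tki, mutation) keys: {self.keys}")


class ParseError(BenchmarkError):
    """A table cell could not be parsed; carries the offending row index."""

    def __init__(self, row, column, value):
        self.row = row
        self.column = column
        super().__init__(f"row {row}: cannot parse {column!r} value {value!r}")


class InsufficientReplicatesError(BenchmarkError):
    """Replicate aggregation needs at least two values."""


class DegenerateLabelsError(BenchmarkError):
    """A ROC curve needs both experimental classes present."""


class ConvergenceError(BenchmarkError):
    """MCMC diagnostics failed after the retry budget.

    Carries the offending diagnostics table in ``diagnostics``.
    """

    def __init__(self, message, diagnostics=None):
        self.diagnostics = diagnostics
        super().__init__(message)
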