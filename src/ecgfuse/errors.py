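"""Exception hierarchy shared across the pipeline."""


class EcgFuseError(Exception):
    """Base class for all package errors."""


class FormatError(EcgFuseError):
    """A file exists but cannot be parsed as the expected format."""


class RecordIOError(EcgFuseError, IOError):
    """Missing or unwritable record/annotation files."""


class DomainError(EcgFuseError, ValueError):
    """An argument is outside its physiological or mathematical domain."""


class DegenerateColumnError(EcgFuseError, ValueError):
    """A column-wise normalizer hit a zero-variance or zero-mean column."""

    def __init__(self, columns, what="zero-variance"):
        self.columns = list(columns)
        super().__init__(
            f"{what} column(s) {self.columns[:10]}"
            + ("..." if len(self.columns) > 10 else "")
        )


class FlatlineBeatError(EcgFuseError, ValueError):
    """A row-wise (per-beat) normalizer hit one or more flatline beats."""

    def __init__(self, rows):
        self.rows = list(rows)
        super().__init__(f"flatline beat row(s) {self.rows[:10]}"
                         + ("..." if len(self.rows) > 10 else ""))


class ConfigurationError(EcgFuseError, ValueError):
    """Invalid class map, network spec, or mismatched model/dataset schemes."""


class IntegrationError(EcgFuseError):
    """Multi-database merge produced no usable beats."""


class TrainingDivergedError(EcgFuseError, ArithmeticError):
    """Loss became non-finite during optimization."""
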