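"""Exception hierarchy shared across the pipeline."""


class DoselogError(Exception):
    """Base class for all package errors."""


class SchemaError(DoselogError):
    """A required column is missing or the file layout is wrong."""


class RowValidationError(DoselogError):
    """A single data row fails validation; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class IntegrityError(DoselogError):
    """A cross-record constraint is violated (e.g. duplicate patient_id)."""


class EmptyLogError(DoselogError):
    """A patient has no cleaned injection days; no observation window exists."""


class UndefinedMetricError(DoselogError):
    """A summary is requested over an empty set or with a zero denominator."""


class ParameterError(DoselogError):
    """A configuration value is outside its valid domain."""


class InvariantError(DoselogError):
    """An internal pipeline precondition was violated (a bug, not bad data)."""
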