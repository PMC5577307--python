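"""Exception hierarchy shared across the package."""


class SoaytelError(Exception):
    """Base class for all package errors."""


class ParameterError(SoaytelError, ValueError):
    """Invalid simulation or run parameters."""


class DomainError(SoaytelError, ValueError):
    """A quantity is outside its mathematical domain (e.g. RTL <= 0, E <= 1)."""


class InputError(SoaytelError, ValueError):
    """Malformed input data (curves too short, missing wells, ...)."""


class SchemaError(SoaytelError, ValueError):
    """A delimited-text table violates its documented schema.

    Carries the offending row/column where known.
    """

    def __init__(self, message: str, row=None, column=None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


class EstimationError(SoaytelError, RuntimeError):
    """A curve or model estimate could not be produced."""


class UsageError(SoaytelError, ValueError):
    """An operation was called with incompatible arguments (e.g. LRT on
    non-nested fits)."""
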