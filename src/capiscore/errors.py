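"""Exception types shared across the package."""


class CapiscoreError(Exception):
    """Base class for all package errors."""


class ValidationError(CapiscoreError, ValueError):
    """A domain object or input table violates an invariant."""


class TableFormatError(ValidationError):
    """A delimited-text input is malformed; carries row context."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        ctx = []
        if row is not None:
            ctx.append(f"row {row}")
        if field is not None:
            ctx.append(f"field '{field}'")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.row = row
        self.field = field


class ContractError(CapiscoreError, ValueError):
    """A caller violated an operation's precondition."""
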