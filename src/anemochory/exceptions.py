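"""Exception types shared across the package."""


class DomainError(ValueError):
    """An input violates a physical or mathematical precondition.

    The message always names the offending quantity so CLI users can map
    the failure back to a column or flag.
    """


class SchemaError(ValueError):
    """A table fails validation against its declared schema.

    Carries the (1-based, header-exclusive) row number and column name
    when the failure is row-local.
    """

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        super().__init__(message)
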