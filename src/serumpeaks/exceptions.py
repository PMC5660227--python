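"""Exception hierarchy shared across the pipeline."""


class SerumPeaksError(Exception):
    """Base class for all package errors."""


class ValidationError(SerumPeaksError, ValueError):
    """A domain object violates one of its invariants."""


class ParameterError(SerumPeaksError, ValueError):
    """A caller-supplied parameter is out of range or inconsistent."""


class EmptyInputError(SerumPeaksError, ValueError):
    """An input file, table or selection contains no usable data."""


class SpectrumParseError(SerumPeaksError, ValueError):
    """A spectrum file could not be parsed; carries the failure location."""

    def __init__(self, message: str, *, offset: int | None = None):
        if offset is not None:
            message = f"{message} (near byte offset {offset})"
        super().__init__(message)
        self.offset = offset
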