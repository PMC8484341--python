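"""Exception hierarchy."""


class MapsFCError(Exception):
    """Base class for package errors."""


class FormatError(MapsFCError):
    """A file does not conform to the expected binary/text layout."""


class CorruptionError(FormatError):
    """A file is structurally valid but its payload is truncated or damaged."""

    def __init__(self, message: str, byte_offset: int | None = None):
        if byte_offset is not None:
            message = f"{message} (at byte offset {byte_offset})"
        super().__init__(message)
        self.byte_offset = byte_offset


class LinkageError(MapsFCError):
    """Pulse file and list-mode table share no events."""


class ContractError(MapsFCError):
    """An operation was called with arguments violating its preconditions."""


class GatingError(MapsFCError):
    """Automatic threshold/window fitting failed; manual values required."""


class DegenerateDataError(MapsFCError):
    """The data carry no usable variation for the requested analysis."""
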