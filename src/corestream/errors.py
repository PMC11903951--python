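"""Exception hierarchy for the acquisition stack.

CRC failures are deliberately a distinct type from framing errors: a CRC
failure is recoverable by resynchronisation, a framing error (wrong length,
bad header) is a caller bug or an unusable file.
"""


class CoreStreamError(Exception):
    """Base class for all package errors."""


class ConfigError(CoreStreamError):
    """Invalid channel or emulator configuration."""


class FramingError(CoreStreamError):
    """Byte buffer cannot be a frame (wrong length, truncated)."""


class CrcError(CoreStreamError):
    """Embedded CRC does not match the recomputed CRC (recoverable)."""


class ProtocolError(CoreStreamError):
    """Unknown or malformed command byte sequence."""


class IncompleteCommandError(ProtocolError):
    """A multi-byte command was truncated; caller may buffer more bytes."""

    def __init__(self, needed: int, got: int):
        super().__init__(f"command needs {needed} bytes, got {got}")
        self.needed = needed
        self.got = got


class StateError(CoreStreamError):
    """Operation not permitted in the device's current mode."""


class AlignmentError(CoreStreamError):
    """Device and reference edge sequences cannot be paired."""


class InsufficientDataError(CoreStreamError):
    """Not enough samples/edges to compute the requested statistic."""


class FormatError(CoreStreamError):
    """Malformed stored file (bad magic, version, or header)."""


class ParseError(FormatError):
    """Malformed CSV content; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class SessionError(CoreStreamError):
    """Acquisition session handshake or transport failure."""
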