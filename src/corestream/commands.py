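"""Base-station -> device command protocol (1–3 byte commands) and replies.

Every command is one tag byte plus at most two payload bytes, so the whole
instruction set fits the device's 1/2/3-byte command constraint.  Channel
selection rides on the two Start commands as an 8-bit mask (bit k-1 <-> AIk,
bits 6–7 <-> AX1/AX2).  The digital-output trigger packs its two output bits
into the tag byte itself and is therefore a single byte; the DAC trigger is
two bytes.

The byte values below are defined by this package (used identically by the
emulator and the client); they are self-consistent, not claimed identical to
any firmware's table.  Device replies (version, status) travel as
length-prefixed UTF-8 text records on the same byte stream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .errors import IncompleteCommandError, ProtocolError

__all__ = [
    "CommandTag",
    "Command",
    "Mode",
    "DeviceStatus",
    "encode_command",
    "decode_command",
    "command_length",
    "encode_reply",
    "decode_reply",
]


class Mode(enum.Enum):
    """Device operating mode.

    IDLE: standing by, accepting commands.  LIVE: streaming frames sampled
    from the analog front end.  SIMULATED: identical framing, but channel
    values are synthesized on the device.  Transitions are Idle<->Live and
    Idle<->Simulated only; Stop returns to Idle from anywhere.
    """

    IDLE = "idle"
    LIVE = "live"
    SIMULATED = "simulated"


class CommandTag(enum.Enum):
    STOP = 0x00
    START_LIVE = 0x01
    START_SIMULATED = 0x02
    SET_SAMPLING_RATE = 0x03
    SET_BATTERY_THRESHOLD = 0x04
    SET_API_MODE = 0x05
    GET_VERSION = 0x06
    GET_STATUS = 0x07
    SET_DAC = 0x08
    TRIGGER_DIGITAL_OUT = 0xB0  # low two bits of the tag byte carry O1,O2


_TRIGGER_BASE = 0xB0

# tag byte -> total encoded length (trigger handled separately)
_LENGTHS = {
    CommandTag.STOP: 1,
    CommandTag.START_LIVE: 2,
    CommandTag.START_SIMULATED: 2,
    CommandTag.SET_SAMPLING_RATE: 3,
    CommandTag.SET_BATTERY_THRESHOLD: 2,
    CommandTag.SET_API_MODE: 2,
    CommandTag.GET_VERSION: 1,
    CommandTag.GET_STATUS: 1,
    CommandTag.SET_DAC: 2,
    CommandTag.TRIGGER_DIGITAL_OUT: 1,
}

# payload range per tag: (min, max) of the single integer argument
_ARG_RANGE = {
    CommandTag.START_LIVE: (0x01, 0xFF),
    CommandTag.START_SIMULATED: (0x01, 0xFF),
    CommandTag.SET_SAMPLING_RATE: (1, 0xFFFF),
    CommandTag.SET_BATTERY_THRESHOLD: (0, 63),
    CommandTag.SET_API_MODE: (0, 1),
    CommandTag.SET_DAC: (0, 255),
    CommandTag.TRIGGER_DIGITAL_OUT: (0, 3),
}


@dataclass(frozen=True)
class Command:
    """A tagged instruction with at most one integer argument.

    Argument meaning by tag: Start* — channel mask; SetSamplingRate — Hz;
    SetBatteryThreshold — level 0..63; SetApiMode — 0 native, 1 legacy
    compatibility; SetDac — DAC level 0..255; TriggerDigitalOut — 2-bit
    value (O1 << 1 | O2).  Tag-only commands carry ``arg=None``.
    """

    tag: CommandTag
    arg: Optional[int] = None

    @classmethod
    def trigger_digital_out(cls, o1: int, o2: int) -> "Command":
        return cls(CommandTag.TRIGGER_DIGITAL_OUT, (o1 & 1) << 1 | (o2 & 1))


def _check_arg(cmd: Command) -> None:
    rng = _ARG_RANGE.get(cmd.tag)
    if rng is None:
        if cmd.arg is not None:
            raise ValueError(f"{cmd.tag.name} takes no argument")
        return
    if cmd.arg is None:
        raise ValueError(f"{cmd.tag.name} requires an argument")
    lo, hi = rng
    if not lo <= cmd.arg <= hi:
        raise ValueError(f"{cmd.tag.name} argument {cmd.arg} outside {lo}..{hi}")


def encode_command(cmd: Command) -> bytes:
    """Serialise to 1–3 bytes; multibyte integers are little-endian."""
    _check_arg(cmd)
    tag = cmd.tag
    if tag is CommandTag.TRIGGER_DIGITAL_OUT:
        return bytes([_TRIGGER_BASE | cmd.arg])
    n = _LENGTHS[tag]
    if n == 1:
        return bytes([tag.value])
    if n == 2:
        return bytes([tag.value, cmd.arg])
    return bytes([tag.value]) + cmd.arg.to_bytes(2, "little")


def command_length(tag_byte: int) -> int:
    """Total encoded length implied by a tag byte (for stream chunking)."""
    if tag_byte & 0xFC == _TRIGGER_BASE:
        return 1
    try:
        return _LENGTHS[CommandTag(tag_byte)]
    except ValueError:
        raise ProtocolError(f"unknown command tag byte {tag_byte:#04x}")


def decode_command(data: bytes) -> Command:
    """Inverse of :func:`encode_command` on its image.

    Unknown tag bytes raise :class:`ProtocolError`; a recognised multi-byte
    command cut short raises :class:`IncompleteCommandError` so a streaming
    caller can buffer and retry.
    """
    if not data:
        raise ProtocolError("empty command")
    tag_byte = data[0]
    n = command_length(tag_byte)
    if len(data) < n:
        raise IncompleteCommandError(needed=n, got=len(data))
    if len(data) > n:
        raise ProtocolError(f"{n}-byte command followed by {len(data) - n} extra bytes")
    if tag_byte & 0xFC == _TRIGGER_BASE:
        return Command(CommandTag.TRIGGER_DIGITAL_OUT, tag_byte & 0x3)
    tag = CommandTag(tag_byte)
    if n == 1:
        return Command(tag)
    if n == 2:
        cmd = Command(tag, data[1])
    else:
        cmd = Command(tag, int.from_bytes(data[1:3], "little"))
    _check_arg(cmd)
    return cmd


@dataclass
class DeviceStatus:
    """Snapshot the device reports in response to GetStatus."""

    firmware_version: str = "emu-1.0.0"
    reference_voltage_mv: float = 1100.0
    adc_attenuation_mode: str = "none"
    attenuation_factor: float = 1.0
    battery_level: float = 100.0
    battery_low: bool = False
    mode: Mode = Mode.IDLE

    def to_text(self) -> str:
        return ";".join(
            [
                f"version={self.firmware_version}",
                f"vref_mv={self.reference_voltage_mv:g}",
                f"attenuation={self.adc_attenuation_mode}",
                f"attenuation_factor={self.attenuation_factor:g}",
                f"battery={self.battery_level:.1f}",
                f"battery_low={int(self.battery_low)}",
                f"mode={self.mode.value}",
            ]
        )

    @classmethod
    def from_text(cls, text: str) -> "DeviceStatus":
        fields = dict(item.split("=", 1) for item in text.split(";"))
        return cls(
            firmware_version=fields["version"],
            reference_voltage_mv=float(fields["vref_mv"]),
            adc_attenuation_mode=fields["attenuation"],
            attenuation_factor=float(fields["attenuation_factor"]),
            battery_level=float(fields["battery"]),
            battery_low=bool(int(fields["battery_low"])),
            mode=Mode(fields["mode"]),
        )


def encode_reply(text: str) -> bytes:
    """Length-prefixed UTF-8 text record (device -> base station)."""
    payload = text.encode("utf-8")
    if len(payload) > 0xFF:
        raise ValueError("reply too long for a 1-byte length prefix")
    return bytes([len(payload)]) + payload


def decode_reply(data: bytes) -> tuple[str, bytes]:
    """Parse one reply record; returns (text, remaining bytes)."""
    if not data:
        raise IncompleteCommandError(needed=1, got=0)
    n = data[0]
    if len(data) < 1 + n:
        raise IncompleteCommandError(needed=1 + n, got=len(data))
    return data[1 : 1 + n].decode("utf-8"), data[1 + n :]
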