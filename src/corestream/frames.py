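"""Bit-exact data-frame codec with CRC-4 integrity and sequence numbering.

A frame carries one sampling tick: up to six 12-bit internal ADC channels
(AI1..AI6, the MCU's 0–1.1 V converter), up to two 24-bit external ADC
channels (AX1, AX2), four digital I/O bits, a 12-bit sequence number for
loss detection and a 4-bit CRC for corruption detection.  Frame length is
therefore variable, from 4 bytes (one internal channel) to 18 bytes (all
eight channels).

Canonical bit layout (MSB-first bit string, serialised big-endian)::

    [pad to byte boundary] [AI samples, 12 b each, AI1 first]
    [AX samples, 24 b each, AX1 first] [I1 I2 O1 O2] [seq, 12 b] [CRC, 4 b]

Zero padding sits at the *front* so that the sequence number and CRC are at
fixed offsets from the end of every frame, which is what lets a receiver
resynchronise on frame tails after corruption.  The CRC is the CRC-4
remainder (polynomial x^4 + x + 1, init 0, no reflection, no final XOR)
over the whole frame with the CRC nibble zeroed.

This layout is canonical for this package; it reproduces every published
frame length but is not claimed wire-compatible with any particular
firmware build.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ConfigError, CrcError, FramingError

__all__ = [
    "INTERNAL_CHANNELS",
    "EXTERNAL_CHANNELS",
    "INTERNAL_BITS",
    "EXTERNAL_BITS",
    "SEQ_BITS",
    "SEQ_MODULUS",
    "CRC_BITS",
    "ChannelConfig",
    "DataFrame",
    "IntegrityReport",
    "frame_size",
    "crc4",
    "encode_frame",
    "decode_frame",
    "seq_gap",
]

INTERNAL_CHANNELS = ("AI1", "AI2", "AI3", "AI4", "AI5", "AI6")
EXTERNAL_CHANNELS = ("AX1", "AX2")

INTERNAL_BITS = 12
EXTERNAL_BITS = 24
SEQ_BITS = 12
SEQ_MODULUS = 1 << SEQ_BITS  # 4096
CRC_BITS = 4
#: seq (12) + CRC (4) + digital I1,I2,O1,O2 (4)
OVERHEAD_BITS = SEQ_BITS + CRC_BITS + 4

_CRC_POLY = 0x3  # x^4 + x + 1, top term implicit (ITU G.704 convention)


@dataclass(frozen=True)
class ChannelConfig:
    """Which analog channels are active; fixes the frame layout and size.

    Channel order is canonical and fixed (AI1 < ... < AI6; AX1 < AX2)
    regardless of the order given at construction.  Between one and eight
    channels may be active for a frame to exist; an empty configuration is
    representable but rejected by :func:`frame_size` and the codec.
    """

    internal: tuple[str, ...] = ()
    external: tuple[str, ...] = ()

    def __post_init__(self):
        internal = tuple(sorted(set(self.internal), key=INTERNAL_CHANNELS.index))
        external = tuple(sorted(set(self.external), key=EXTERNAL_CHANNELS.index))
        for name in internal:
            if name not in INTERNAL_CHANNELS:
                raise ConfigError(f"unknown internal channel {name!r}")
        for name in external:
            if name not in EXTERNAL_CHANNELS:
                raise ConfigError(f"unknown external channel {name!r}")
        object.__setattr__(self, "internal", internal)
        object.__setattr__(self, "external", external)

    @classmethod
    def from_channels(cls, names: Iterable[str]) -> "ChannelConfig":
        names = list(names)
        return cls(
            internal=tuple(n for n in names if n in INTERNAL_CHANNELS),
            external=tuple(n for n in names if n in EXTERNAL_CHANNELS),
        )

    @classmethod
    def from_numbers(cls, numbers: Iterable[int]) -> "ChannelConfig":
        """Build from the client's channel numbering: 1–6 = AI1–AI6, 7/8 = AX1/AX2."""
        names = []
        for k in numbers:
            if 1 <= k <= 6:
                names.append(f"AI{k}")
            elif k in (7, 8):
                names.append(f"AX{k - 6}")
            else:
                raise ConfigError(f"channel number {k} out of range 1..8")
        return cls.from_channels(names)

    @classmethod
    def from_mask(cls, mask: int) -> "ChannelConfig":
        """Build from an 8-bit mask: bit k-1 <-> AIk, bits 6–7 <-> AX1–AX2."""
        if not 0 < mask <= 0xFF:
            raise ConfigError(f"channel mask {mask:#x} out of range 0x01..0xff")
        return cls(
            internal=tuple(INTERNAL_CHANNELS[i] for i in range(6) if mask >> i & 1),
            external=tuple(EXTERNAL_CHANNELS[i] for i in range(2) if mask >> (6 + i) & 1),
        )

    def to_mask(self) -> int:
        mask = 0
        for name in self.internal:
            mask |= 1 << INTERNAL_CHANNELS.index(name)
        for name in self.external:
            mask |= 1 << (6 + EXTERNAL_CHANNELS.index(name))
        return mask

    @property
    def channels(self) -> tuple[str, ...]:
        return self.internal + self.external

    @property
    def n_active(self) -> int:
        return len(self.internal) + len(self.external)

    def bit_depth(self, name: str) -> int:
        if name in INTERNAL_CHANNELS:
            return INTERNAL_BITS
        if name in EXTERNAL_CHANNELS:
            return EXTERNAL_BITS
        raise ConfigError(f"unknown channel {name!r}")


@dataclass(frozen=True)
class DataFrame:
    """One decoded sampling tick.

    ``internal``/``external`` map active channel names to raw quantization
    levels (12-bit: 0..4095; 24-bit: 0..2^24-1).  ``seq`` wraps modulo 4096.
    """

    seq: int
    internal: Mapping[str, int] = field(default_factory=dict)
    external: Mapping[str, int] = field(default_factory=dict)
    i1: int = 0
    i2: int = 0
    o1: int = 0
    o2: int = 0

    def sample(self, name: str) -> int:
        if name in self.internal:
            return self.internal[name]
        return self.external[name]

    def __eq__(self, other):
        if not isinstance(other, DataFrame):
            return NotImplemented
        return (
            self.seq == other.seq
            and dict(self.internal) == dict(other.internal)
            and dict(self.external) == dict(other.external)
            and (self.i1, self.i2, self.o1, self.o2)
            == (other.i1, other.i2, other.o1, other.o2)
        )


@dataclass
class IntegrityReport:
    """Stream bookkeeping: valid frames, seq-gap losses, CRC failures, resyncs.

    ``frames_lost`` is accumulated only from sequence gaps between frames
    whose CRC validated; a frame dropped for CRC failure is counted once in
    ``crc_failures`` and never double-counted as lost.
    """

    frames_ok: int = 0
    frames_lost: int = 0
    crc_failures: int = 0
    resync_events: int = 0

    def merge(self, other: "IntegrityReport") -> None:
        self.frames_ok += other.frames_ok
        self.frames_lost += other.frames_lost
        self.crc_failures += other.crc_failures
        self.resync_events += other.resync_events


def frame_size(config: ChannelConfig) -> int:
    """Encoded frame length in bytes for *config*.

    ceil((20 + 12·nAI + 24·nAX) / 8): the 20 overhead bits are the 12-bit
    sequence number, 4-bit CRC and four digital bits.  Ranges from 4 bytes
    (one internal channel) to 18 bytes (all eight channels).
    """
    n_int, n_ext = len(config.internal), len(config.external)
    if not 1 <= n_int + n_ext <= 8:
        raise ConfigError(
            f"{n_int + n_ext} active channels; need between 1 and 8"
        )
    bits = OVERHEAD_BITS + INTERNAL_BITS * n_int + EXTERNAL_BITS * n_ext
    return (bits + 7) // 8


def crc4(payload: bytes) -> int:
    """CRC-4 remainder over *payload* bits in transmission (MSB-first) order.

    Polynomial x^4 + x + 1, initial value 0, no reflection, no final XOR —
    the remainder of M(x)·x^4 divided by the generator.  The caller must
    already have zeroed the CRC nibble inside *payload*.
    """
    if len(payload) == 0:
        raise ValueError("empty payload")
    crc = 0
    for byte in payload:
        for shift in range(7, -1, -1):
            top = (crc >> 3) ^ (byte >> shift & 1)
            crc = (crc << 1) & 0xF
            if top & 1:
                crc ^= _CRC_POLY
    return crc


def _frame_bits(frame: DataFrame, config: ChannelConfig) -> int:
    """Pack the frame into an integer per the canonical layout, CRC nibble zero."""
    value = 0
    for name in config.internal:
        try:
            sample = frame.internal[name]
        except KeyError:
            raise ConfigError(f"frame missing sample for active channel {name}")
        if not 0 <= sample < (1 << INTERNAL_BITS):
            raise ValueError(f"{name} sample {sample} out of 12-bit range")
        value = value << INTERNAL_BITS | sample
    for name in config.external:
        try:
            sample = frame.external[name]
        except KeyError:
            raise ConfigError(f"frame missing sample for active channel {name}")
        if not 0 <= sample < (1 << EXTERNAL_BITS):
            raise ValueError(f"{name} sample {sample} out of 24-bit range")
        value = value << EXTERNAL_BITS | sample
    for bit in (frame.i1, frame.i2, frame.o1, frame.o2):
        if bit not in (0, 1):
            raise ValueError(f"digital bit {bit!r} must be 0 or 1")
        value = value << 1 | bit
    if not 0 <= frame.seq < SEQ_MODULUS:
        raise ValueError(f"seq {frame.seq} out of 12-bit range")
    value = value << SEQ_BITS | frame.seq
    return value << CRC_BITS  # CRC nibble zeroed


def encode_frame(frame: DataFrame, config: ChannelConfig) -> bytes:
    """Serialise *frame* to exactly ``frame_size(config)`` bytes.

    Extraneous sample keys (channels not active in *config*) are rejected so
    that encode/decode round-trip equality is meaningful.
    """
    if set(frame.internal) - set(config.internal) or set(frame.external) - set(
        config.external
    ):
        raise ConfigError("frame carries samples for inactive channels")
    n = frame_size(config)
    raw = _frame_bits(frame, config).to_bytes(n, "big")
    crc = crc4(raw)
    return raw[:-1] + bytes([raw[-1] | crc])


def decode_frame(data: bytes, config: ChannelConfig) -> DataFrame:
    """Parse one frame; raises :class:`CrcError` on corruption.

    The input must be exactly ``frame_size(config)`` bytes (a shorter or
    longer buffer is a :class:`FramingError`, not a CRC failure).
    """
    n = frame_size(config)
    if len(data) != n:
        raise FramingError(f"expected {n} bytes, got {len(data)}")
    stored = data[-1] & 0xF
    zeroed = data[:-1] + bytes([data[-1] & 0xF0])
    computed = crc4(zeroed)
    if computed != stored:
        raise CrcError(f"CRC mismatch: stored {stored:#x}, computed {computed:#x}")
    value = int.from_bytes(data, "big") >> CRC_BITS
    seq = value & (SEQ_MODULUS - 1)
    value >>= SEQ_BITS
    o2 = value & 1
    o1 = value >> 1 & 1
    i2 = value >> 2 & 1
    i1 = value >> 3 & 1
    value >>= 4
    external: dict[str, int] = {}
    for name in reversed(config.external):
        external[name] = value & ((1 << EXTERNAL_BITS) - 1)
        value >>= EXTERNAL_BITS
    internal: dict[str, int] = {}
    for name in reversed(config.internal):
        internal[name] = value & ((1 << INTERNAL_BITS) - 1)
        value >>= INTERNAL_BITS
    return DataFrame(
        seq=seq,
        internal={k: internal[k] for k in config.internal},
        external={k: external[k] for k in config.external},
        i1=i1,
        i2=i2,
        o1=o1,
        o2=o2,
    )


def seq_gap(prev_seq: int, curr_seq: int) -> int:
    """Frames lost between two consecutively *received* sequence numbers.

    ``(curr - prev - 1) mod 4096`` — consecutive frames give 0.  The value
    is only interpretable while true loss bursts stay below 4095 frames.
    """
    if not (0 <= prev_seq < SEQ_MODULUS and 0 <= curr_seq < SEQ_MODULUS):
        raise ValueError("sequence numbers must be 12-bit")
    return (curr_seq - prev_seq - 1) % SEQ_MODULUS
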