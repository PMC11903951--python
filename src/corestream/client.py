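"""Base-station acquisition client.

Connects to a device (real TCP endpoint or in-process emulator), performs
the handshake (firmware version, reference voltage and attenuation mode
from device status), configures the sampling rate and channels, then
streams frames: each received frame is CRC-checked, sequence gaps are
accumulated as lost frames, corrupted stretches are recovered by byte-wise
resynchronisation, and raw quantization levels are optionally converted to
millivolts.

Loss accounting rules:

* ``frames_lost`` comes only from sequence gaps between CRC-valid frames,
  ``(curr - prev - 1) mod 4096``, so wraparound of the 12-bit counter is
  transparent and bursts shorter than 4095 frames are counted exactly.
* A frame dropped for CRC failure is counted once in ``crc_failures``; gap
  accounting is skipped across the failure so it is never double-counted
  as lost.
"""

from __future__ import annotations

import socket
from dataclasses import dataclass, field
from typing import Optional, Protocol

from .commands import (
    Command,
    CommandTag,
    DeviceStatus,
    Mode,
    decode_reply,
    encode_command,
)
from .emulator import DeviceEmulator, DeviceShutdown
from .errors import CrcError, FramingError, IncompleteCommandError, SessionError
from .frames import (
    ChannelConfig,
    DataFrame,
    IntegrityReport,
    decode_frame,
    frame_size,
    seq_gap,
)
from .storage import Recording, Row

__all__ = [
    "raw_to_mv",
    "resync",
    "Transport",
    "InMemoryTransport",
    "TcpTransport",
    "ClientSession",
]

VREF_EXTERNAL_MV = 3300.0  # default full scale for the 24-bit external ADC


def raw_to_mv(
    raw: int, bit_depth: int, vref_mv: float, attenuation_factor: float = 1.0
) -> float:
    """Convert a quantization level to millivolts.

    ``raw / (2^bit_depth - 1) * vref_mv * attenuation_factor`` — strictly
    increasing in ``raw`` and exact at both endpoints (0 maps to 0 mV, full
    scale maps to ``vref_mv * attenuation_factor``).
    """
    if not 0 <= raw < (1 << bit_depth):
        raise ValueError(f"raw value {raw} outside 0..2^{bit_depth}-1")
    return raw / ((1 << bit_depth) - 1) * vref_mv * attenuation_factor


def resync(
    buffer: bytes,
    config: ChannelConfig,
    prev_seq: Optional[int] = None,
    window: int = 16,
) -> tuple[list[DataFrame], int]:
    """Recover frames from a buffer that may start mid-frame or be corrupted.

    Slides one byte at a time; a candidate frame is accepted only when its
    CRC validates *and* its sequence number is plausibly consecutive with
    the previously accepted frame (gap below *window*) when one exists.
    The first acceptance, with no prior frame, is on CRC alone.  Returns
    the recovered frames and the number of bytes skipped over.
    """
    fsize = frame_size(config)
    frames: list[DataFrame] = []
    prev = prev_seq
    pos = 0
    discarded = 0
    while pos + fsize <= len(buffer):
        try:
            frame = decode_frame(buffer[pos : pos + fsize], config)
        except (CrcError, FramingError):
            pos += 1
            discarded += 1
            continue
        if prev is not None and seq_gap(prev, frame.seq) >= window:
            pos += 1
            discarded += 1
            continue
        frames.append(frame)
        prev = frame.seq
        pos += fsize
    return frames, discarded


class Transport(Protocol):
    def send(self, data: bytes) -> None: ...

    def recv(self) -> bytes:
        """Return at least one byte, or b'' when the stream has ended."""
        ...

    def close(self) -> None: ...


class InMemoryTransport:
    """Threadless transport that drives a sans-IO emulator on demand.

    ``recv`` pumps the emulator one tick at a time until output appears,
    so the client consumes every emitted frame and the emulator's generated
    tick count is an exact conservation reference for integrity tests.
    """

    def __init__(self, emulator: DeviceEmulator):
        self.emulator = emulator

    def send(self, data: bytes) -> None:
        self.emulator.feed_bytes(data)

    def recv(self) -> bytes:
        emu = self.emulator
        out = emu.take_output()
        while not out and emu.mode is not Mode.IDLE:
            try:
                emu.pump(1)
            except DeviceShutdown:
                break
            out = emu.take_output()
        return out

    def close(self) -> None:
        pass


class TcpTransport:
    def __init__(self, host: str, port: int, timeout_s: float = 10.0):
        self._sock = socket.create_connection((host, port), timeout=timeout_s)

    def send(self, data: bytes) -> None:
        self._sock.sendall(data)

    def recv(self) -> bytes:
        try:
            return self._sock.recv(65536)
        except socket.timeout:
            raise SessionError("transport receive timed out")

    def close(self) -> None:
        try:
            self._sock.close()
        except OSError:
            pass


@dataclass
class ClientSession:
    """One acquisition session against a device endpoint.

    ``vref_mv`` is learned from the device status during :meth:`connect`;
    the external 24-bit channels use a separate full-scale reference
    (``vref_ext_mv``, default 3300 mV).  Conversion to millivolts is
    applied unless ``raw_only`` is set.
    """

    transport: Transport
    channels: ChannelConfig
    sampling_rate_hz: int = 1000
    raw_only: bool = False
    vref_ext_mv: float = VREF_EXTERNAL_MV
    plausibility_window: int = 16
    firmware_version: str = ""
    vref_mv: float = 1100.0
    attenuation_factor: float = 1.0
    status: Optional[DeviceStatus] = None
    report: IntegrityReport = field(default_factory=IntegrityReport)
    _buf: bytearray = field(default_factory=bytearray)

    # -- handshake ---------------------------------------------------------

    def _read_reply(self) -> str:
        while True:
            try:
                text, rest = decode_reply(bytes(self._buf))
            except IncompleteCommandError:
                more = self.transport.recv()
                if not more:
                    raise SessionError("device closed during handshake")
                self._buf.extend(more)
                continue
            except Exception as exc:
                raise SessionError(f"bad handshake reply: {exc}")
            self._buf = bytearray(rest)
            return text

    def connect(self) -> DeviceStatus:
        """Query version and status, then push the sampling rate."""
        self.transport.send(encode_command(Command(CommandTag.GET_VERSION)))
        self.firmware_version = self._read_reply()
        self.transport.send(encode_command(Command(CommandTag.GET_STATUS)))
        self.status = DeviceStatus.from_text(self._read_reply())
        self.vref_mv = self.status.reference_voltage_mv
        self.attenuation_factor = self.status.attenuation_factor
        self.transport.send(
            encode_command(Command(CommandTag.SET_SAMPLING_RATE, self.sampling_rate_hz))
        )
        return self.status

    def start(self, simulated: bool = True) -> None:
        tag = CommandTag.START_SIMULATED if simulated else CommandTag.START_LIVE
        self.transport.send(encode_command(Command(tag, self.channels.to_mask())))

    def stop(self) -> None:
        self.transport.send(encode_command(Command(CommandTag.STOP)))

    # -- streaming ---------------------------------------------------------

    def _row(self, frame: DataFrame) -> Row:
        raw = tuple(frame.sample(ch) for ch in self.channels.channels)
        mv = None
        if not self.raw_only:
            mv = tuple(
                raw_to_mv(
                    value,
                    self.channels.bit_depth(ch),
                    self.vref_mv if ch.startswith("AI") else self.vref_ext_mv,
                    self.attenuation_factor,
                )
                for ch, value in zip(self.channels.channels, raw)
            )
        return Row(frame.seq, frame.i1, frame.i2, frame.o1, frame.o2, raw, mv)

    def stream_acquire(
        self,
        n_frames: Optional[int] = None,
        duration_s: Optional[float] = None,
        simulated: bool = True,
    ) -> tuple[Recording, IntegrityReport]:
        """Acquire until *n_frames* sampling ticks have been observed.

        A "tick" is a valid frame, a gap slot, or a CRC-failed frame — i.e.
        the client stops once the device has demonstrably produced the
        requested number of samples, whether or not they all arrived.  On a
        transport drop the partial recording is returned with its
        truncation flag set.
        """
        if n_frames is None:
            if duration_s is None:
                raise ValueError("give n_frames or duration_s")
            n_frames = int(round(duration_s * self.sampling_rate_hz))
        self.start(simulated=simulated)
        fsize = frame_size(self.channels)
        rec = Recording(
            channels=self.channels,
            sampling_rate_hz=self.sampling_rate_hz,
            vref_mv=self.vref_mv,
            attenuation=self.attenuation_factor,
            firmware_version=self.firmware_version,
            raw_only=self.raw_only,
        )
        report = self.report
        # acquisition always starts at seq 0, so the frame "before" the
        # stream is virtually 4095: losses at the very start are countable
        prev_seq: Optional[int] = 4095
        skip_gap = False
        observed = 0
        resyncing = False
        offset = 0  # scan position while resyncing
        while observed < n_frames:
            if len(self._buf) < fsize + offset:
                more = self.transport.recv()
                if not more:
                    rec.truncated = True
                    break
                self._buf.extend(more)
                continue
            candidate = bytes(self._buf[offset : offset + fsize])
            try:
                frame = decode_frame(candidate, self.channels)
            except CrcError:
                if not resyncing:
                    # the corrupted frame itself: count it once, then scan
                    report.crc_failures += 1
                    report.resync_events += 1
                    observed += 1  # the corrupted frame was a generated tick
                    skip_gap = True
                    resyncing = True
                    offset += fsize
                else:
                    offset += 1
                continue
            if resyncing and prev_seq is not None:
                if seq_gap(prev_seq, frame.seq) >= self.plausibility_window:
                    offset += 1
                    continue
            del self._buf[: offset + fsize]
            offset = 0
            resyncing = False
            if prev_seq is not None:
                gap = seq_gap(prev_seq, frame.seq)
                if skip_gap:
                    pass  # lost-vs-corrupted double counting avoided
                else:
                    report.frames_lost += gap
                    observed += gap
            skip_gap = False
            prev_seq = frame.seq
            report.frames_ok += 1
            observed += 1
            rec.rows.append(self._row(frame))
        self.stop()
        return rec, report
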