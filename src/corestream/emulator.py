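"""Software device emulator: a frame-streaming acquisition board in software.

The emulator honours the command protocol and, in Live or Simulated mode,
generates data frames with:

* timer-quantized sampling cadence — the device times samples with an
  integer number of ticks of an 80 MHz base clock, so the effective period
  is ``round(base_clock/SR)/base_clock`` and only sampling rates that divide
  the base clock sample at exactly ``1/SR``;
* configurable per-channel waveforms (constant, square, sine) evaluated at
  the *true* emitted timestamps and quantized to the channel's bit depth;
* injected packet loss (a set of tick indices that are generated but never
  emitted) and injected corruption (a deterministic single-bit flip in the
  encoded frame);
* a battery model: readings are unaffected while the supply is above the
  regulator dropout, scale down between dropout and shutdown, and the
  device stops emitting below shutdown.

The core is sans-IO (:meth:`DeviceEmulator.feed_bytes` /
:meth:`DeviceEmulator.take_output` / :meth:`DeviceEmulator.pump`), so tests
can drive a full session deterministically with no threads or sockets;
:func:`serve` wraps the same core in a one-client TCP server.  Frame
cadence is logical (timestamps are computed, never slept on), so a 240 s
experiment runs in well under a second.
"""

from __future__ import annotations

import math
import random
import select
import socket
import threading
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from . import commands as cmdmod
from .commands import Command, CommandTag, DeviceStatus, Mode
from .errors import ConfigError, ProtocolError, StateError
from .frames import ChannelConfig, DataFrame, encode_frame

__all__ = [
    "BASE_CLOCK_HZ",
    "WaveformSpec",
    "constant",
    "square",
    "sine",
    "BatteryModel",
    "battery_voltage",
    "apply_battery",
    "EmulatorConfig",
    "DeviceEmulator",
    "DeviceShutdown",
    "effective_sampling_period",
    "EmulatorServer",
    "serve",
]

BASE_CLOCK_HZ = 80_000_000
FIRMWARE_VERSION = "corestream-emu 1.0.0"


class DeviceShutdown(StateError):
    """Battery fell below the shutdown voltage; the device stopped emitting."""


# ---------------------------------------------------------------------------
# timing


def effective_sampling_period(sr_hz: int, base_clock_hz: int = BASE_CLOCK_HZ) -> float:
    """Timer-quantized sampling period in seconds.

    The sample timer counts an integer number of base-clock ticks, so the
    realisable period is ``round(base_clock/SR)/base_clock``.  This equals
    ``1/SR`` exactly iff SR divides the base clock; otherwise each sample is
    early or late by a fixed sub-microsecond amount that accumulates into
    linear drift.
    """
    if sr_hz < 1:
        raise ValueError(f"sampling rate {sr_hz} must be >= 1 Hz")
    if sr_hz > base_clock_hz:
        raise ValueError(f"sampling rate {sr_hz} exceeds base clock {base_clock_hz}")
    q, r = divmod(int(base_clock_hz), int(sr_hz))
    ticks = q + (1 if 2 * r >= sr_hz else 0)  # round to nearest, half away
    return ticks / base_clock_hz


# ---------------------------------------------------------------------------
# waveforms


@dataclass(frozen=True)
class WaveformSpec:
    """A channel stimulus, in quantization levels of the target channel.

    kinds: ``constant(level)``; ``square(freq_hz, low, high)`` — low for the
    first half of each cycle, so rising edges fall at ``(k + 1/2)/f``;
    ``sine(freq_hz, amplitude, offset)``.
    """

    kind: str
    freq_hz: float = 0.0
    level: float = 0.0
    low: float = 0.0
    high: float = 0.0
    amplitude: float = 0.0
    offset: float = 0.0

    def eval(self, t):
        """Waveform value (float levels, pre-quantization) at time(s) *t*."""
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full_like(t, float(self.level))
        elif self.kind == "square":
            phase = np.mod(t * self.freq_hz, 1.0)
            out = np.where(phase < 0.5, float(self.low), float(self.high))
        elif self.kind == "sine":
            out = self.offset + self.amplitude * np.sin(2 * math.pi * self.freq_hz * t)
        else:
            raise ConfigError(f"unknown waveform kind {self.kind!r}")
        return out if out.ndim else float(out)


def constant(level: float) -> WaveformSpec:
    return WaveformSpec("constant", level=level)


def square(freq_hz: float, low: float, high: float) -> WaveformSpec:
    return WaveformSpec("square", freq_hz=freq_hz, low=low, high=high)


def sine(freq_hz: float, amplitude: float, offset: float) -> WaveformSpec:
    return WaveformSpec("sine", freq_hz=freq_hz, amplitude=amplitude, offset=offset)


# ---------------------------------------------------------------------------
# battery


@dataclass(frozen=True)
class BatteryModel:
    """Piecewise-linear Li-ion discharge model.

    Voltage falls linearly from ``v_full`` (4.2 V) to the regulator dropout
    (3.3 V) over the first 95% of the nominal runtime ``capacity_mah /
    draw_ma`` hours, then quickly from dropout to shutdown (3.0 V), reaching
    shutdown at exactly the nominal runtime.  Readings are unaffected above
    dropout (the regulators hold the rail), scale with the sagging supply
    between dropout and shutdown, and the device stops below shutdown.
    """

    v_full: float = 4.2
    v_dropout: float = 3.3
    v_shutdown: float = 3.0
    capacity_mah: float = 900.0
    draw_ma: float = 46.0

    @property
    def runtime_s(self) -> float:
        return self.capacity_mah / self.draw_ma * 3600.0

    def level_percent(self, v: float) -> float:
        span = self.v_full - self.v_shutdown
        return float(np.clip((v - self.v_shutdown) / span * 100.0, 0.0, 100.0))


def battery_voltage(t: float, model: BatteryModel) -> float:
    """Battery voltage at elapsed time *t* seconds; non-increasing."""
    if t < 0:
        raise ValueError("time must be non-negative")
    t_dropout = 0.95 * model.runtime_s
    t_shutdown = model.runtime_s
    if t <= t_dropout:
        frac = t / t_dropout if t_dropout > 0 else 1.0
        return model.v_full - (model.v_full - model.v_dropout) * frac
    fall_rate = (model.v_dropout - model.v_shutdown) / (t_shutdown - t_dropout)
    # the fall continues below shutdown (the device has stopped by then)
    return max(model.v_dropout - fall_rate * (t - t_dropout), 0.0)


def apply_battery(sample: int, v: float, model: BatteryModel, bit_depth: int) -> int:
    """Battery effect on one raw reading.

    Identity while the supply is at or above dropout; between shutdown and
    dropout the sagging rail scales readings by ``v / v_dropout``.
    """
    if v >= model.v_dropout:
        return int(sample)
    scale = max(v, model.v_shutdown) / model.v_dropout
    return int(np.clip(round(sample * scale), 0, (1 << bit_depth) - 1))


# ---------------------------------------------------------------------------
# emulator


def _default_channels() -> ChannelConfig:
    return ChannelConfig.from_mask(0x3F)  # AI1..AI6


@dataclass(frozen=True)
class EmulatorConfig:
    """Full device state for frame generation.

    ``epsilon_override_s`` adds a constant extra spacing on top of the
    timer-quantized period (the structural quantization error is always
    present); ``loss_pattern`` holds tick indices that are generated but not
    emitted; ``corrupt_pattern`` holds tick indices whose encoded frame gets
    a deterministic single-bit flip.
    """

    sampling_rate_hz: int = 1000
    channels: ChannelConfig = field(default_factory=_default_channels)
    base_clock_hz: int = BASE_CLOCK_HZ
    waveforms: dict = field(default_factory=dict)
    epsilon_override_s: float = 0.0
    loss_pattern: frozenset = frozenset()
    corrupt_pattern: frozenset = frozenset()
    rng_seed: int = 0
    battery: BatteryModel = field(default_factory=BatteryModel)
    vref_mv: float = 1100.0
    max_rate_hz: int = 10_000

    def __post_init__(self):
        if self.sampling_rate_hz < 1:
            raise ConfigError("sampling rate must be >= 1 Hz")
        if self.sampling_rate_hz > self.max_rate_hz:
            raise ConfigError(
                f"sampling rate {self.sampling_rate_hz} exceeds cap {self.max_rate_hz}"
            )
        if self.base_clock_hz < self.sampling_rate_hz:
            raise ConfigError("base clock must be at least the sampling rate")


_MID = {12: 2048.0, 24: float(1 << 23)}


class DeviceEmulator:
    """Sans-IO emulated acquisition device.

    Commands arrive via :meth:`feed_bytes`; replies and encoded frames
    accumulate in an output buffer drained by :meth:`take_output`.  Frame
    generation is driven explicitly with :meth:`pump` (encoded bytes) or
    :meth:`step` (decoded frames), so callers control time.
    """

    def __init__(self, config: EmulatorConfig):
        self.config = config
        self.mode = Mode.IDLE
        self.channels = config.channels
        self.sampling_rate_hz = config.sampling_rate_hz
        self.seq = 0
        self.tick = 0
        self.o1 = 0
        self.o2 = 0
        self.dac_level = 0
        self.battery_threshold = 0
        self.api_mode = 0
        self.shut_down = False
        self._out = bytearray()
        self._cmd_buf = bytearray()
        self._rng = random.Random(config.rng_seed)

    # -- timing ------------------------------------------------------------

    @property
    def period_s(self) -> float:
        """Actual inter-frame spacing: quantized period plus any ε override."""
        return (
            effective_sampling_period(self.sampling_rate_hz, self.config.base_clock_hz)
            + self.config.epsilon_override_s
        )

    def timestamp(self, tick: int) -> float:
        return tick * self.period_s

    # -- command handling ----------------------------------------------------

    def feed_bytes(self, data: bytes) -> None:
        """Consume command bytes; partial commands are buffered."""
        self._cmd_buf.extend(data)
        while self._cmd_buf:
            n = cmdmod.command_length(self._cmd_buf[0])
            if len(self._cmd_buf) < n:
                return
            chunk = bytes(self._cmd_buf[:n])
            del self._cmd_buf[:n]
            self.handle_command(cmdmod.decode_command(chunk))

    def handle_command(self, cmd: Command) -> None:
        tag = cmd.tag
        if tag is CommandTag.STOP:
            self.mode = Mode.IDLE
        elif tag in (CommandTag.START_LIVE, CommandTag.START_SIMULATED):
            if self.mode is not Mode.IDLE:
                raise StateError(f"cannot start acquisition from {self.mode.value}")
            self.channels = ChannelConfig.from_mask(cmd.arg)
            self.seq = 0
            self.tick = 0
            self.mode = Mode.LIVE if tag is CommandTag.START_LIVE else Mode.SIMULATED
        elif tag is CommandTag.SET_SAMPLING_RATE:
            if self.mode is not Mode.IDLE:
                raise StateError("sampling rate can only change in idle mode")
            if cmd.arg > self.config.max_rate_hz:
                raise StateError(
                    f"rate {cmd.arg} exceeds device cap {self.config.max_rate_hz}"
                )
            self.sampling_rate_hz = cmd.arg
        elif tag is CommandTag.SET_BATTERY_THRESHOLD:
            self.battery_threshold = cmd.arg
        elif tag is CommandTag.SET_API_MODE:
            self.api_mode = cmd.arg
        elif tag is CommandTag.GET_VERSION:
            self._out += cmdmod.encode_reply(FIRMWARE_VERSION)
        elif tag is CommandTag.GET_STATUS:
            self._out += cmdmod.encode_reply(self.status().to_text())
        elif tag is CommandTag.SET_DAC:
            self.dac_level = cmd.arg
        elif tag is CommandTag.TRIGGER_DIGITAL_OUT:
            self.o1 = cmd.arg >> 1 & 1
            self.o2 = cmd.arg & 1
        else:  # pragma: no cover - tags are exhaustive
            raise ProtocolError(f"unhandled tag {tag}")

    def status(self) -> DeviceStatus:
        v = battery_voltage(self.timestamp(self.tick), self.config.battery)
        return DeviceStatus(
            firmware_version=FIRMWARE_VERSION,
            reference_voltage_mv=self.config.vref_mv,
            adc_attenuation_mode="none",
            attenuation_factor=1.0,
            battery_level=self.config.battery.level_percent(v),
            battery_low=v < self.config.battery.v_dropout,
            mode=self.mode,
        )

    # -- frame generation ----------------------------------------------------

    def _waveform(self, name: str) -> WaveformSpec:
        try:
            return self.config.waveforms[name]
        except KeyError:
            return constant(_MID[self.channels.bit_depth(name)])

    def _quantize(self, name: str, value: float, v_batt: float) -> int:
        depth = self.channels.bit_depth(name)
        raw = int(np.clip(round(value), 0, (1 << depth) - 1))
        return apply_battery(raw, v_batt, self.config.battery, depth)

    def step(self) -> tuple[Optional[DataFrame], float]:
        """Advance one sampling tick.

        Returns ``(frame, timestamp)``; the frame is ``None`` when this
        tick's index is in the injected loss pattern (generated, not
        emitted).  Raises :class:`StateError` in Idle mode and
        :class:`DeviceShutdown` once the battery is below shutdown voltage.
        """
        if self.mode is Mode.IDLE:
            raise StateError("device is idle; send a start command first")
        t = self.timestamp(self.tick)
        v = battery_voltage(t, self.config.battery)
        if v < self.config.battery.v_shutdown:
            self.shut_down = True
            self.mode = Mode.IDLE
            raise DeviceShutdown(f"battery at {v:.2f} V after {t:.0f} s")
        internal = {
            name: self._quantize(name, self._waveform(name).eval(t), v)
            for name in self.channels.internal
        }
        external = {
            name: self._quantize(name, self._waveform(name).eval(t), v)
            for name in self.channels.external
        }
        frame = DataFrame(
            seq=self.seq,
            internal=internal,
            external=external,
            i1=0,
            i2=0,
            o1=self.o1,
            o2=self.o2,
        )
        emitted = self.tick not in self.config.loss_pattern
        corrupt = self.tick in self.config.corrupt_pattern
        self.seq = (self.seq + 1) % 4096
        self.tick += 1
        if not emitted:
            return None, t
        if corrupt:
            frame = replace(frame)  # encoded copy is corrupted in pump()
        return frame, t

    def pump(self, n_ticks: int) -> int:
        """Generate *n_ticks* ticks, appending encoded frames to the output.

        Returns the number of frames actually emitted (ticks minus injected
        losses).  Corruption-pattern ticks are emitted with one bit flipped
        at a seed-deterministic position.
        """
        emitted = 0
        for _ in range(n_ticks):
            tick = self.tick
            frame, _t = self.step()
            if frame is None:
                continue
            data = encode_frame(frame, self.channels)
            if tick in self.config.corrupt_pattern:
                pos = self._rng.randrange(len(data) * 8)
                data = bytearray(data)
                data[pos // 8] ^= 1 << (pos % 8)
                data = bytes(data)
            self._out += data
            emitted += 1
        return emitted

    def frames(self, n_ticks: int) -> Iterator[tuple[Optional[DataFrame], float]]:
        for _ in range(n_ticks):
            yield self.step()

    def take_output(self) -> bytes:
        out = bytes(self._out)
        self._out.clear()
        return out

    # -- vectorized analysis path --------------------------------------------

    def waveform_trace(self, duration_s: float = None, n_ticks: int = None):
        """Quantized sample trace for the active channels, loss-free.

        Vectorized fast path for timing analysis: returns ``(timestamps,
        {channel: int array})`` where timestamps are the *true* emission
        times ``n * (period + ε)``.  Loss and corruption injection do not
        apply (they affect transport, not the sampled waveform); the battery
        scaling does.
        """
        if n_ticks is None:
            if duration_s is None:
                raise ValueError("give duration_s or n_ticks")
            n_ticks = int(round(duration_s / self.period_s))
        t = np.arange(n_ticks) * self.period_s
        v = np.array([battery_voltage(ti, self.config.battery) for ti in (0.0, t[-1] if n_ticks else 0.0)])
        traces = {}
        for name in self.channels.channels:
            depth = self.channels.bit_depth(name)
            values = np.clip(np.round(self._waveform(name).eval(t)), 0, (1 << depth) - 1)
            if v.min() < self.config.battery.v_dropout:
                # slow path only when the run actually crosses dropout
                vt = np.array([battery_voltage(ti, self.config.battery) for ti in t])
                scale = np.clip(vt, self.config.battery.v_shutdown, None) / self.config.battery.v_dropout
                values = np.clip(np.round(values * np.where(vt >= self.config.battery.v_dropout, 1.0, scale)), 0, (1 << depth) - 1)
            traces[name] = values.astype(np.int64)
        return t, traces


# ---------------------------------------------------------------------------
# TCP serving


class EmulatorServer:
    """One-client TCP wrapper around a :class:`DeviceEmulator`.

    Streams frames as fast as the client consumes them (logical cadence;
    timestamps are never slept on).  The session closes cleanly on client
    disconnect, returning the device to Idle.
    """

    def __init__(self, emulator: DeviceEmulator, host: str = "127.0.0.1", port: int = 0):
        self.emulator = emulator
        self._sock = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._sock.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._sock.bind((host, port))
        self._sock.listen(1)
        self.host, self.port = self._sock.getsockname()
        self._stop = threading.Event()
        self._thread = threading.Thread(target=self._run, daemon=True)

    def start(self) -> "EmulatorServer":
        self._thread.start()
        return self

    def _run(self) -> None:
        self._sock.settimeout(5.0)
        try:
            conn, _addr = self._sock.accept()
        except (socket.timeout, OSError):
            return
        conn.setblocking(False)
        emu = self.emulator
        try:
            while not self._stop.is_set():
                readable, _, _ = select.select([conn], [], [], 0.0005)
                if readable:
                    try:
                        data = conn.recv(4096)
                    except BlockingIOError:
                        data = b""
                    except (ConnectionResetError, OSError):
                        break
                    if data == b"":
                        break  # client disconnected
                    try:
                        emu.feed_bytes(data)
                    except (ProtocolError, StateError) as exc:
                        conn.sendall(cmdmod.encode_reply(f"error={exc}"))
                if emu.mode is not Mode.IDLE:
                    try:
                        emu.pump(64)
                    except DeviceShutdown:
                        pass
                out = emu.take_output()
                if out:
                    try:
                        conn.sendall(out)
                    except (BrokenPipeError, ConnectionResetError, OSError):
                        break
        finally:
            emu.mode = Mode.IDLE
            conn.close()
            self._sock.close()

    def stop(self) -> None:
        self._stop.set()
        self._thread.join(timeout=5.0)


def serve(emulator: DeviceEmulator, host: str = "127.0.0.1", port: int = 0) -> EmulatorServer:
    """Start serving *emulator* on TCP; returns the running server."""
    return EmulatorServer(emulator, host, port).start()
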