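"""Acquire from an emulated device and account for injected packet loss.

The emulator honours the command protocol and streams frames; here it is
told to drop three specific frames.  The client detects every loss from
the gaps in the 12-bit sequence number and converts raw quantization
levels to millivolts using the device-reported 1100 mV reference.
"""

from corestream import (
    ChannelConfig,
    ClientSession,
    DeviceEmulator,
    EmulatorConfig,
    InMemoryTransport,
    sine,
)

channels = ChannelConfig(internal=("AI1",))
emulator = DeviceEmulator(
    EmulatorConfig(
        sampling_rate_hz=1000,
        channels=channels,
        waveforms={"AI1": sine(freq_hz=2.0, amplitude=1500, offset=2048)},
        loss_pattern=frozenset({10, 11, 500}),
    )
)

session = ClientSession(InMemoryTransport(emulator), channels, sampling_rate_hz=1000)
status = session.connect()
print(f"firmware {session.firmware_version}, vref {session.vref_mv:g} mV, "
      f"battery {status.battery_level:.0f}%")

recording, report = session.stream_acquire(duration_s=1.0)
print(f"rows received: {recording.n_rows}")
print(f"frames ok: {report.frames_ok}, lost: {report.frames_lost} "
      "(the three injected drops, found via sequence gaps)")
row = recording.rows[250]
print(f"row NSeq={row.nseq}: raw={row.raw[0]} levels = {row.mv[0]:.2f} mV "
      "(raw/4095 x 1100 mV)")
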