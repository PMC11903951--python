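"""Write an SD-card binary log, corrupt one frame, convert to CSV.

On-card acquisition supports two modes: all six internal channels at
2000 Hz, or all internal plus one/two external channels at 100 Hz.  The
log is a 16-byte header followed by back-to-back encoded frames; the
converter decodes each frame, skipping (and counting) any that fail the
CRC.
"""

import io

from corestream import (
    ChannelConfig,
    ClientSession,
    DeviceEmulator,
    EmulatorConfig,
    InMemoryTransport,
    convert_sd_to_csv,
    frame_size,
    sine,
    write_sd,
)
from corestream.storage import SD_HEADER_LEN

channels = ChannelConfig.from_numbers([1, 2, 3, 4, 5, 6])  # all internal @ 2000 Hz
emulator = DeviceEmulator(
    EmulatorConfig(
        sampling_rate_hz=2000,
        channels=channels,
        waveforms={ch: sine(5, 1000, 2048) for ch in channels.channels},
    )
)
session = ClientSession(InMemoryTransport(emulator), channels, 2000, raw_only=True)
session.connect()
recording, _ = session.stream_acquire(n_frames=200)

binary = io.BytesIO()
n = write_sd(recording, binary)
print(f"wrote {n} frames, file size {SD_HEADER_LEN} + {n} x "
      f"{frame_size(channels)} = {binary.tell()} bytes")

# flip one bit in frame 7 to emulate a bad sector
blob = bytearray(binary.getvalue())
blob[SD_HEADER_LEN + 7 * frame_size(channels) + 2] ^= 0x01

csv_out = io.StringIO()
summary = convert_sd_to_csv(io.BytesIO(bytes(blob)), csv_out)
print(f"converted rows: {summary.rows}, CRC failures skipped: "
      f"{summary.crc_failures}, truncated: {summary.truncated}")
print("first CSV lines:")
for line in csv_out.getvalue().splitlines()[:10]:
    print(" ", line)
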