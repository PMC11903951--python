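"""Encode and decode one data frame, and see the CRC catch corruption.

A frame packs one sampling tick: active-channel samples, four digital
bits, a 12-bit sequence number and a 4-bit CRC.  Frame length depends only
on which channels are active (4 bytes for one internal channel, up to 18
bytes for all eight).
"""

from corestream import ChannelConfig, DataFrame, decode_frame, encode_frame, frame_size
from corestream.errors import CrcError

config = ChannelConfig(internal=("AI1", "AI2"), external=("AX1",))
print(f"active channels: {config.channels}")
print(f"frame size: {frame_size(config)} bytes")  # ceil((20 + 2*12 + 24)/8) = 9

frame = DataFrame(
    seq=41,
    internal={"AI1": 2048, "AI2": 4095},
    external={"AX1": 8_388_608},
    i1=1,
)
wire = encode_frame(frame, config)
print(f"encoded: {wire.hex()} ({len(wire)} bytes)")

back = decode_frame(wire, config)
print(f"decoded seq={back.seq}, AI1={back.internal['AI1']}, AX1={back.external['AX1']}")
assert back == frame  # encoding is lossless

# flip one bit anywhere and the 4-bit CRC flags it
corrupted = bytearray(wire)
corrupted[3] ^= 0x04
try:
    decode_frame(bytes(corrupted), config)
except CrcError as exc:
    print(f"single-bit corruption detected: {exc}")
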