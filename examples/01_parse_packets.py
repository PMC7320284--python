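"""Decode a TGAM byte stream: framing, checksums, flagged corruption.

Builds a tiny stream from the codec itself (two raw-wave small packets and
one big packet), flips one payload byte, and parses it back.
"""

from tgamopt import BigPacket, parse_stream, serialize_big, serialize_small

big = BigPacket(
    poor_signal=0,
    bands=(420_000, 180_000, 90_000, 70_000, 55_000, 40_000, 25_000, 15_000),
    attention=56,
    meditation=44,
)
stream = serialize_small(-120) + serialize_small(95) + serialize_big(big)

# corrupt one payload byte of the second small packet (offset 8, payload at 11..14)
corrupted = bytearray(stream)
corrupted[12] ^= 0x40

for label, data in [("clean", stream), ("corrupted", bytes(corrupted))]:
    print(f"--- {label} stream ({len(data)} bytes) ---")
    for pkt in parse_stream(data):
        print(f"  offset {pkt.byte_offset:3d}  checksum_ok={pkt.checksum_ok}  {pkt}")

print(
    "\nThe corrupted small packet is still emitted, flagged checksum_ok=False: "
    "the codec reports, the pipeline rejects."
)
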