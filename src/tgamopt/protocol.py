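"""Bit-exact codec for the TGAM binary serial protocol.

The ThinkGear Asic Module (TGAM) interleaves two record types on its serial
link: 8-byte *small packets* carrying one raw-wave ADC sample every 2 ms, and
36-byte *big packets* (one per 512 small packets) carrying poor-signal
quality, eight spectral band powers, and the firmware's attention and
meditation values.

Both record types share the frame ``AA AA <len> <payload...> <checksum>``
where ``len`` is 0x04 for small and 0x20 for big packets, and the checksum is
the low byte of the bitwise inversion of the payload sum.  The big-packet
payload layout used here is the de-facto ThinkGear dialect::

    02 <poor_signal> 83 18 <24 band bytes> 04 <attention> 05 <meditation>

Band powers are 3-byte little-endian unsigned integers in the order Delta,
Theta, LowAlpha, HighAlpha, LowBeta, HighBeta, LowGamma, MidGamma.

Parsing is deliberately tolerant: a packet whose frame is intact but whose
checksum mismatches is still emitted, flagged ``checksum_ok=False`` —
rejection policy belongs to the attention pipeline, not the codec.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

__all__ = [
    "SYNC_BYTE",
    "SMALL_PACKET_LEN",
    "BIG_PACKET_LEN",
    "SMALLS_PER_BIG",
    "SMALL_PERIOD_S",
    "BAND_NAMES",
    "RAW_MIN",
    "RAW_MAX",
    "SmallPacket",
    "BigPacket",
    "ByteStream",
    "compute_checksum",
    "parse_raw_value",
    "splice_band_value",
    "parse_stream",
    "serialize_small",
    "serialize_big",
]

logger = logging.getLogger(__name__)

SYNC_BYTE = 0xAA
SMALL_PAYLOAD_LEN = 0x04
BIG_PAYLOAD_LEN = 0x20
SMALL_PACKET_LEN = 8
BIG_PACKET_LEN = 36

#: one raw-wave sample every 2 ms; one big packet after every 512 small ones
SMALL_PERIOD_S = 0.002
SMALLS_PER_BIG = 512

CODE_RAW = 0x80
CODE_POOR_SIGNAL = 0x02
CODE_BANDS = 0x83
BAND_BYTES_LEN = 0x18  # 24 = 8 bands x 3 bytes
CODE_ATTENTION = 0x04
CODE_MEDITATION = 0x05

BAND_NAMES = (
    "delta",
    "theta",
    "low_alpha",
    "high_alpha",
    "low_beta",
    "high_beta",
    "low_gamma",
    "mid_gamma",
)

RAW_MIN = -32767
RAW_MAX = 32768


@dataclass(frozen=True)
class SmallPacket:
    """One 2 ms raw-wave sample (dimensionless ADC units)."""

    raw_value: int
    checksum_ok: bool = True
    byte_offset: int = 0


@dataclass(frozen=True)
class BigPacket:
    """Per-period summary: poor signal, 8 band powers, attention, meditation."""

    poor_signal: int
    bands: tuple
    attention: int
    meditation: int
    checksum_ok: bool = True
    byte_offset: int = 0


@dataclass(frozen=True)
class ByteStream:
    """A raw TGAM byte sequence plus a human-readable source descriptor."""

    data: bytes
    source: str = "<memory>"

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ByteStream":
        p = Path(path)
        return cls(p.read_bytes(), source=str(p))


Packet = Union[SmallPacket, BigPacket]


def compute_checksum(payload: Iterable[int]) -> int:
    """Low 8 bits of the bitwise inversion (XOR 0xFFFFFFFF) of the payload sum."""
    return (sum(payload) ^ 0xFFFFFFFF) & 0xFF


def parse_raw_value(high: int, low: int) -> int:
    """Splice a high/low byte pair into a signed raw-wave sample.

    The module transmits eight bits high then eight bits low; values above
    32768 wrap to the negative range, giving [-32767, 32768] exactly.
    """
    if not (0 <= high <= 0xFF and 0 <= low <= 0xFF):
        raise ValueError("raw bytes must be in 0..255")
    v = (high << 8) | low
    return v - 65536 if v > 32768 else v


def splice_band_value(b_low: int, b_mid: int, b_high: int) -> int:
    """Splice a 3-byte little-endian band power (lowest byte transmitted first)."""
    for b in (b_low, b_mid, b_high):
        if not 0 <= b <= 0xFF:
            raise ValueError("band bytes must be in 0..255")
    return b_low | (b_mid << 8) | (b_high << 16)


def serialize_small(raw_value: int) -> bytes:
    """Serialize one raw sample as an 8-byte small packet."""
    if not RAW_MIN <= raw_value <= RAW_MAX:
        raise ValueError(f"raw_value {raw_value} outside [{RAW_MIN}, {RAW_MAX}]")
    v = raw_value + 65536 if raw_value < 0 else raw_value
    payload = bytes((CODE_RAW, 0x02, (v >> 8) & 0xFF, v & 0xFF))
    return bytes((SYNC_BYTE, SYNC_BYTE, SMALL_PAYLOAD_LEN)) + payload + bytes(
        (compute_checksum(payload),)
    )


def serialize_big(packet: BigPacket) -> bytes:
    """Serialize a :class:`BigPacket` as a 36-byte big packet."""
    if not 0 <= packet.poor_signal <= 200:
        raise ValueError("poor_signal must be in 0..200")
    if len(packet.bands) != 8:
        raise ValueError("exactly 8 band powers required")
    for b in packet.bands:
        if not 0 <= b < (1 << 24):
            raise ValueError("band power must fit in 24 bits")
    for name in ("attention", "meditation"):
        if not 0 <= getattr(packet, name) <= 100:
            raise ValueError(f"{name} must be in 0..100")
    payload = bytearray((CODE_POOR_SIGNAL, packet.poor_signal, CODE_BANDS, BAND_BYTES_LEN))
    for b in packet.bands:
        payload += bytes((b & 0xFF, (b >> 8) & 0xFF, (b >> 16) & 0xFF))
    payload += bytes((CODE_ATTENTION, packet.attention, CODE_MEDITATION, packet.meditation))
    assert len(payload) == BIG_PAYLOAD_LEN
    return bytes((SYNC_BYTE, SYNC_BYTE, BIG_PAYLOAD_LEN)) + bytes(payload) + bytes(
        (compute_checksum(payload),)
    )


def _parse_big_payload(payload: bytes, checksum_ok: bool, offset: int) -> BigPacket:
    bands = tuple(
        splice_band_value(payload[4 + 3 * i], payload[5 + 3 * i], payload[6 + 3 * i])
        for i in range(8)
    )
    return BigPacket(
        poor_signal=payload[1],
        bands=bands,
        attention=payload[29],
        meditation=payload[31],
        checksum_ok=checksum_ok,
        byte_offset=offset,
    )


def parse_stream(stream: Union[ByteStream, bytes, bytearray]) -> list:
    """Scan a byte stream for sync marks and decode every recognizable packet.

    Unrecognizable bytes are skipped with a logged resync event; a truncated
    trailing packet is logged as a partial record, never raised.  Packets with
    failing checksums are emitted flagged.
    """
    if isinstance(stream, ByteStream):
        data, source = stream.data, stream.source
    else:
        data, source = bytes(stream), "<memory>"
    out: list = []
    i, n = 0, len(data)
    skipped = 0
    while i < n:
        if data[i] != SYNC_BYTE:
            i += 1
            skipped += 1
            continue
        if i + 2 >= n:
            logger.debug("partial record at end of %s (offset %d)", source, i)
            break
        if data[i + 1] != SYNC_BYTE:
            i += 1
            skipped += 1
            continue
        plen = data[i + 2]
        if plen == SMALL_PAYLOAD_LEN:
            total = SMALL_PACKET_LEN
        elif plen == BIG_PAYLOAD_LEN:
            total = BIG_PACKET_LEN
        else:
            i += 1
            skipped += 1
            continue
        if i + total > n:
            logger.debug("truncated trailing packet in %s at offset %d", source, i)
            break
        payload = data[i + 3 : i + total - 1]
        ok = data[i + total - 1] == compute_checksum(payload)
        if plen == SMALL_PAYLOAD_LEN:
            out.append(SmallPacket(parse_raw_value(payload[2], payload[3]), ok, i))
        else:
            out.append(_parse_big_payload(payload, ok, i))
        # a failed checksum may mean a misaligned fake frame, not just a
        # corrupted payload: consume the frame only when it verifies, else
        # emit it flagged and resync one byte at a time
        i += total if ok else 1
    if skipped:
        logger.debug("resynced past %d unparseable bytes in %s", skipped, source)
    return out
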