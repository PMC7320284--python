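"""Codec: checksum, splicing, framing, round-trips, resync."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgamopt import (
    BIG_PACKET_LEN,
    RAW_MAX,
    RAW_MIN,
    SMALL_PACKET_LEN,
    BigPacket,
    SmallPacket,
    compute_checksum,
    parse_raw_value,
    parse_stream,
    serialize_big,
    serialize_small,
    splice_band_value,
)
from conftest import random_big_packet


@pytest.mark.parametrize(
    "payload,expected",
    [
        ([], 0xFF),
        ([0x80, 0x02, 0x00, 0x00], 0x7D),  # sum 0x82 -> invert low byte
        ([0xFF], 0x00),  # complement identity at low byte 0xFF
        ([0x80, 0x7F], 0x00),
        (list(range(256)), (0x80 ^ 0xFF)),  # sum 32640, low byte 0x80
    ],
)
def test_checksum_examples(payload, expected):
    assert compute_checksum(payload) == expected


def test_raw_splice_examples():
    assert parse_raw_value(0x00, 0x00) == 0
    assert parse_raw_value(0x80, 0x00) == 32768
    assert parse_raw_value(0x80, 0x01) == -32767


def test_raw_splice_exhaustive_range():
    """All 65536 byte pairs map exactly onto [-32767, 32768]."""
    values = {parse_raw_value(h, l) for h in range(256) for l in range(256)}
    assert values == set(range(RAW_MIN, RAW_MAX + 1))


@pytest.mark.parametrize(
    "triplet,expected", [((0, 0, 0), 0), ((1, 0, 0), 1), ((0, 1, 0), 256), ((0, 0, 1), 65536)]
)
def test_band_splice_lowest_byte_first(triplet, expected):
    assert splice_band_value(*triplet) == expected


def test_serialized_lengths():
    assert len(serialize_small(0)) == SMALL_PACKET_LEN == 8
    pkt = BigPacket(0, (0,) * 8, 50, 50)
    assert len(serialize_big(pkt)) == BIG_PACKET_LEN == 36


def test_small_packet_worked_bytes():
    assert serialize_small(0) == bytes([0xAA, 0xAA, 0x04, 0x80, 0x02, 0x00, 0x00, 0x7D])


def test_serialize_small_range_error():
    with pytest.raises(ValueError):
        serialize_small(RAW_MAX + 1)
    with pytest.raises(ValueError):
        serialize_small(RAW_MIN - 1)


def test_serialize_big_field_validation(rng):
    good = random_big_packet(rng)
    for bad in (
        {"poor_signal": 201},
        {"attention": 101},
        {"meditation": -1},
        {"bands": (1 << 24,) + (0,) * 7},
    ):
        fields = {**good.__dict__, **bad}
        fields.pop("checksum_ok"), fields.pop("byte_offset")
        with pytest.raises(ValueError):
            serialize_big(BigPacket(**fields))


@settings(derandomize=True, max_examples=200)
@given(st.integers(RAW_MIN, RAW_MAX))
def test_small_roundtrip_identity(raw):
    (pkt,) = parse_stream(serialize_small(raw))
    assert isinstance(pkt, SmallPacket)
    assert pkt.raw_value == raw
    assert pkt.checksum_ok


@settings(derandomize=True, max_examples=100)
@given(
    st.integers(0, 200),
    st.tuples(*[st.integers(0, (1 << 24) - 1)] * 8),
    st.integers(0, 100),
    st.integers(0, 100),
)
def test_big_roundtrip_identity(ps, bands, att, med):
    pkt = BigPacket(ps, bands, att, med)
    (parsed,) = parse_stream(serialize_big(pkt))
    assert parsed == pkt


def test_checksum_byte_validates_by_construction(rng):
    data = serialize_big(random_big_packet(rng))
    assert data[-1] == compute_checksum(data[3:-1])


@pytest.mark.parametrize("kind", ["small", "big"])
def test_single_payload_byte_flip_always_flags(kind, rng):
    """Flipping any single payload byte must flip checksum_ok."""
    if kind == "small":
        data = serialize_small(-1234)
        payload_span = range(3, 7)
    else:
        data = serialize_big(random_big_packet(rng))
        payload_span = range(3, 35)
    for idx in payload_span:
        for mask in (0x01, 0x80, int(rng.integers(1, 256))):
            buf = bytearray(data)
            buf[idx] ^= mask
            packets = parse_stream(bytes(buf))
            assert packets and packets[0].byte_offset == 0
            assert not packets[0].checksum_ok, f"flip at byte {idx} mask {mask:#x} undetected"


def test_stream_cadence_roundtrip(rng):
    """512 valid smalls + 1 big parse back as 513 packets in input order."""
    raws = [int(x) for x in rng.integers(-400, 401, 512)]
    big = random_big_packet(rng)
    data = b"".join(serialize_small(r) for r in raws) + serialize_big(big)
    packets = parse_stream(data)
    assert len(packets) == 513
    assert [p.raw_value for p in packets[:-1]] == raws
    assert replace(packets[-1], byte_offset=0) == big


def test_truncated_trailing_packet_is_dropped_not_raised(rng):
    data = serialize_small(10) + serialize_big(random_big_packet(rng))[:20]
    packets = parse_stream(data)
    assert len(packets) == 1
    assert packets[0].raw_value == 10


def test_garbage_between_packets_resyncs():
    data = serialize_small(1) + bytes([0x00, 0xAA, 0x13]) + serialize_small(2)
    packets = parse_stream(data)
    assert [p.raw_value for p in packets] == [1, 2]


@pytest.mark.parametrize("n_corrupt", [1, 3, 5])
def test_resync_bounded_loss(n_corrupt, rng):
    """Corrupting k interior bytes loses at most k+2 packets; the rest parse
    identically to the uncorrupted stream."""
    raws = [int(x) for x in rng.integers(-300, 301, 60)]
    data = b"".join(serialize_small(r) for r in raws)
    clean = {p.byte_offset: p for p in parse_stream(data)}
    for _ in range(10):
        buf = bytearray(data)
        # interior bytes only (leave first and last packet intact)
        positions = rng.choice(np.arange(8, len(buf) - 8), size=n_corrupt, replace=False)
        for pos in positions:
            buf[pos] ^= int(rng.integers(1, 256))
        parsed = {p.byte_offset: p for p in parse_stream(bytes(buf))}
        surviving = {
            off
            for off, p in parsed.items()
            if off in clean and p.raw_value == clean[off].raw_value and p.checksum_ok
        }
        lost = set(clean) - surviving
        assert len(lost) <= n_corrupt + 2
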