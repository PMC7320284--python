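"""Plain-text interchange: JSONL packet dumps, CSV summaries, output tables."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import pandas as pd

from .blink import BlinkEvent
from .pipeline import AttentionOutput
from .protocol import BAND_NAMES, BigPacket, SmallPacket

__all__ = [
    "write_packets_jsonl",
    "read_packets_jsonl",
    "big_packets_to_frame",
    "write_big_packets_csv",
    "outputs_to_frame",
    "write_outputs",
    "write_blink_events_jsonl",
]

PathLike = Union[str, Path]


def _packet_record(pkt) -> dict:
    rec = asdict(pkt)
    rec["type"] = "small" if isinstance(pkt, SmallPacket) else "big"
    if isinstance(pkt, BigPacket):
        rec["bands"] = list(pkt.bands)
    return rec


def write_packets_jsonl(packets: Iterable, path: PathLike) -> None:
    with open(path, "w") as fh:
        for pkt in packets:
            fh.write(json.dumps(_packet_record(pkt)) + "\n")


def read_packets_jsonl(path: PathLike) -> List:
    packets = []
    with open(path) as fh:
        for line in fh:
            rec = json.loads(line)
            kind = rec.pop("type")
            if kind == "small":
                packets.append(SmallPacket(**rec))
            else:
                rec["bands"] = tuple(rec["bands"])
                packets.append(BigPacket(**rec))
    return packets


def big_packets_to_frame(packets: Iterable) -> pd.DataFrame:
    rows = []
    for pkt in packets:
        if not isinstance(pkt, BigPacket):
            continue
        row = {
            "byte_offset": pkt.byte_offset,
            "poor_signal": pkt.poor_signal,
            **dict(zip(BAND_NAMES, pkt.bands)),
            "attention": pkt.attention,
            "meditation": pkt.meditation,
            "checksum_ok": pkt.checksum_ok,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_big_packets_csv(packets: Iterable, path: PathLike) -> None:
    big_packets_to_frame(packets).to_csv(path, index=False)


def outputs_to_frame(outputs: Sequence[AttentionOutput]) -> pd.DataFrame:
    rows = [
        {
            "packet_index": o.packet_index,
            "raw_attention": o.raw_attention,
            "corrected": o.corrected_attention,
            "smoothed": o.smoothed_attention,
            "level": o.level,
            "reason": o.validation.reason,
        }
        for o in outputs
    ]
    return pd.DataFrame(rows)


def write_outputs(outputs: Sequence[AttentionOutput], path: PathLike, fmt: str = "csv") -> None:
    frame = outputs_to_frame(outputs)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "jsonl":
        frame.to_json(path, orient="records", lines=True)
    else:
        raise ValueError("format must be 'csv' or 'jsonl'")


def write_blink_events_jsonl(events: Sequence[BlinkEvent], path: PathLike) -> None:
    with open(path, "w") as fh:
        for ev in events:
            fh.write(json.dumps(asdict(ev)) + "\n")
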