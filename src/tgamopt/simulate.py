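"""Synthetic TGAM stream generator with ground truth.

Emulates the statistical structure of a real single-node recording so every
pipeline stage is testable without hardware:

* raw-wave baseline noise with >95% of samples within +/-350 ADC units,
  clipped to the observed extremes (max 528, min -427);
* blink excursions — short biphasic pulses whose onset step is at least the
  detection threshold (>= 1000);
* one big packet after every 512 small packets, whose attention-meditation
  pair is drawn only from the retained classification rectangles (null-value
  areas never emitted) and whose attention follows a bounded random walk
  (at most one level per step);
* an 8-20 point attention dip on the first big packet after each blink,
  snapped back onto a retained attention value;
* band powers scaled so regularized values stay below the reference
  thresholds, with optional anomaly injection;
* optional packet corruption: one payload byte flipped after the checksum is
  computed, so corrupted packets always fail verification.

Identical seed and config reproduce the byte stream exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .boundaries import DEFAULT_BAND_SCALES
from .levels import DEFAULT_LEVEL_TABLE, LevelTable
from .protocol import (
    BAND_NAMES,
    BIG_PACKET_LEN,
    SMALL_PERIOD_S,
    SMALLS_PER_BIG,
    BigPacket,
    serialize_big,
    serialize_small,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "synthesize_raw_trace",
    "simulate",
    "simulate_big_packets",
    "emit_calibration_set",
]

BIG_PERIOD_S = SMALLS_PER_BIG * SMALL_PERIOD_S  # 1.024 s between big packets


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic session.

    ``blink_schedule`` is either an explicit list of blink times (seconds) or
    a mean rate (blinks per second); ``raw_noise_sd`` of 170 puts ~96% of
    baseline samples within +/-350.  ``band_anomaly_rate`` is the fraction of
    big packets with >= 3 bands pushed above their thresholds;
    ``corruption_rate`` is the per-packet probability of a payload byte flip.
    """

    duration_s: float = 10.0
    seed: int = 0
    blink_schedule: Union[Sequence[float], float, None] = None
    raw_noise_sd: float = 170.0
    raw_max: int = 528
    raw_min: int = -427
    corruption_rate: float = 0.0
    dip_band: Tuple[int, int] = (8, 20)
    attention_walk_sd: float = 1.0
    poor_signal_rate: float = 0.0
    band_scales: Tuple[float, ...] = DEFAULT_BAND_SCALES.scale
    band_anomaly_rate: float = 0.0
    blink_amplitude: Tuple[float, float] = (1200.0, 1800.0)
    blink_duration_s: float = 0.2
    level_table: LevelTable = DEFAULT_LEVEL_TABLE

    def __post_init__(self):
        if not 0 <= self.corruption_rate < 1:
            raise ValueError("corruption_rate must be in [0, 1)")
        if not self.raw_min < 0 < self.raw_max:
            raise ValueError("raw_min < 0 < raw_max required")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.blink_amplitude[0] < 1000:
            raise ValueError("blink amplitude must reach the detection threshold")


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    blink_times: List[float] = field(default_factory=list)
    corrupted_packet_indices: List[int] = field(default_factory=list)
    true_attention_series: List[int] = field(default_factory=list)
    emitted_am_pairs: List[Tuple[int, int]] = field(default_factory=list)
    dip_big_indices: List[int] = field(default_factory=list)
    anomalous_big_indices: List[int] = field(default_factory=list)


def _resolve_blink_times(cfg: SimConfig, rng: np.random.Generator) -> List[float]:
    bs = cfg.blink_schedule
    if bs is None:
        return []
    if isinstance(bs, (int, float)):
        # rate-based: exponential gaps floored above the big-packet period so
        # at most one blink dips any given big packet
        times, t = [], 0.0
        floor = BIG_PERIOD_S + 0.1
        while True:
            t += max(rng.exponential(1.0 / bs), floor)
            if t >= cfg.duration_s - cfg.blink_duration_s:
                return times
            times.append(t)
    times = sorted(float(t) for t in bs)
    if any(t <= SMALL_PERIOD_S or t >= cfg.duration_s for t in times):
        raise ValueError("blink times must lie inside the session")
    if len(times) > 1 and min(np.diff(times)) < BIG_PERIOD_S:
        raise ValueError(
            "blink spacing below the big-packet period is infeasible with dips enabled"
        )
    return times


def synthesize_raw_trace(
    n_samples: int,
    blink_times: Sequence[float],
    cfg: SimConfig = SimConfig(),
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Baseline noise plus biphasic blink excursions, one sample per 2 ms.

    The onset step of each excursion equals the drawn amplitude (>= 1200 by
    default), so the consecutive-sample difference criterion always fires.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base = rng.normal(0.0, cfg.raw_noise_sd, n_samples)
    raw = np.clip(np.rint(base), cfg.raw_min, cfg.raw_max).astype(int)
    dur = max(6, int(round(cfg.blink_duration_s / SMALL_PERIOD_S)))
    half = dur // 2
    profile = np.concatenate(
        [np.linspace(0.97, -0.25, half), np.linspace(-0.25, 0.0, dur - half)]
    )
    for t in blink_times:
        i0 = int(round(t / SMALL_PERIOD_S))
        if i0 < 1 or i0 >= n_samples:
            continue
        amp = rng.uniform(*cfg.blink_amplitude)
        raw[i0] = raw[i0 - 1] + int(round(amp))  # onset step is exactly amp
        j_end = min(i0 + dur, n_samples - 1)
        for k, j in enumerate(range(i0 + 1, j_end + 1)):
            raw[j] = int(round(base[j] + amp * profile[min(k, dur - 1)]))
    return raw


def _draw_band_fracs(rng: np.random.Generator, anomalous: bool) -> np.ndarray:
    """Regularized band fractions: lognormal bulk capped below the reference
    thresholds; anomalies push >= 3 bands well above them."""
    u = np.minimum(rng.lognormal(np.log(0.15), 0.6, 8), 0.58)
    if anomalous:
        k = int(rng.integers(3, 9))
        idx = rng.choice(8, size=k, replace=False)
        u[idx] = rng.uniform(0.70, 0.95, k)
    return u


class _BigPacketProcess:
    """Bounded attention walk + meditation draw + band generation."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.values = cfg.level_table.valid_attention_values()
        self.pos = len(self.values) // 2 + int(rng.integers(-5, 6))
        self.prev_pair: Optional[Tuple[int, int]] = None

    def _snap_dip(self, att: int) -> int:
        lo, hi = self.cfg.dip_band
        dip = int(self.rng.integers(lo, hi + 1))
        target = att - dip
        window = [v for v in self.values if att - hi <= v <= att - lo]
        pool = window if window else self.values
        return min(pool, key=lambda v: (abs(v - target), v))

    def step(self, dip: bool) -> Tuple[int, int, int, np.ndarray, bool]:
        rng, cfg = self.rng, self.cfg
        move = int(np.clip(round(rng.normal(0.0, cfg.attention_walk_sd)), -1, 1))
        self.pos = int(np.clip(self.pos + move, 0, len(self.values) - 1))
        true_att = self.values[self.pos]
        emitted = self._snap_dip(true_att) if dip else true_att
        lo, hi = cfg.level_table.meditation_bounds(emitted)
        med = int(rng.integers(lo, hi + 1))
        while self.prev_pair == (emitted, med):
            med = int(rng.integers(lo, hi + 1))
        self.prev_pair = (emitted, med)
        anomalous = bool(rng.random() < cfg.band_anomaly_rate)
        fracs = _draw_band_fracs(rng, anomalous)
        bands = tuple(int(f * s) for f, s in zip(fracs, cfg.band_scales))
        if rng.random() < cfg.poor_signal_rate:
            ps = int(rng.choice([26, 51, 55, 200]))
        else:
            ps = 0
        return true_att, emitted, med, (ps, bands), anomalous


def _corrupt(data: bytes, rng: np.random.Generator) -> bytes:
    """Flip one payload byte after checksum computation."""
    buf = bytearray(data)
    idx = int(rng.integers(3, len(buf) - 1))
    buf[idx] ^= int(rng.integers(1, 256))
    return bytes(buf)


def simulate(cfg: SimConfig = SimConfig()) -> Tuple[bytes, GroundTruth]:
    """Generate a full interleaved byte stream plus its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    blink_times = _resolve_blink_times(cfg, rng)
    n_small = int(round(cfg.duration_s / SMALL_PERIOD_S))
    n_big = n_small // SMALLS_PER_BIG
    raw = synthesize_raw_trace(n_small, blink_times, cfg, rng)
    dip_bigs = sorted(
        {
            int(round(t / SMALL_PERIOD_S)) // SMALLS_PER_BIG
            for t in blink_times
            if int(round(t / SMALL_PERIOD_S)) // SMALLS_PER_BIG < n_big
        }
    )
    proc = _BigPacketProcess(cfg, rng)
    gt = GroundTruth(blink_times=list(blink_times), dip_big_indices=list(dip_bigs))
    chunks: List[bytes] = []
    packet_index = 0
    small_i = 0
    for b in range(n_big):
        for _ in range(SMALLS_PER_BIG):
            data = serialize_small(int(raw[small_i]))
            if cfg.corruption_rate and rng.random() < cfg.corruption_rate:
                data = _corrupt(data, rng)
                gt.corrupted_packet_indices.append(packet_index)
            chunks.append(data)
            packet_index += 1
            small_i += 1
        true_att, emitted, med, (ps, bands), anomalous = proc.step(b in dip_bigs)
        gt.true_attention_series.append(true_att)
        gt.emitted_am_pairs.append((emitted, med))
        if anomalous:
            gt.anomalous_big_indices.append(b)
        data = serialize_big(BigPacket(ps, bands, emitted, med))
        if cfg.corruption_rate and rng.random() < cfg.corruption_rate:
            data = _corrupt(data, rng)
            gt.corrupted_packet_indices.append(packet_index)
        chunks.append(data)
        packet_index += 1
    # trailing small packets of an incomplete final period
    while small_i < n_small:
        data = serialize_small(int(raw[small_i]))
        if cfg.corruption_rate and rng.random() < cfg.corruption_rate:
            data = _corrupt(data, rng)
            gt.corrupted_packet_indices.append(packet_index)
        chunks.append(data)
        packet_index += 1
        small_i += 1
    return b"".join(chunks), gt


def simulate_big_packets(
    cfg: SimConfig, n: int
) -> Tuple[bytes, List[BigPacket], GroundTruth]:
    """Generate ``n`` big packets only (no raw-wave interleaving).

    Same generative model as :func:`simulate`; useful for exercising the
    big-packet validation chain at session scale without the 512x small-packet
    byte volume.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    proc = _BigPacketProcess(cfg, rng)
    gt = GroundTruth()
    chunks: List[bytes] = []
    packets: List[BigPacket] = []
    for b in range(n):
        true_att, emitted, med, (ps, bands), anomalous = proc.step(False)
        gt.true_attention_series.append(true_att)
        gt.emitted_am_pairs.append((emitted, med))
        if anomalous:
            gt.anomalous_big_indices.append(b)
        pkt = BigPacket(ps, bands, emitted, med)
        packets.append(pkt)
        data = serialize_big(pkt)
        if cfg.corruption_rate and rng.random() < cfg.corruption_rate:
            data = _corrupt(data, rng)
            gt.corrupted_packet_indices.append(b)
        chunks.append(data)
    return b"".join(chunks), packets, gt


def emit_calibration_set(
    cfg: SimConfig,
    n: int,
    outlier_fraction: float = 0.05,
    am_outlier_fraction: float = 0.0,
) -> pd.DataFrame:
    """Big-packet payload rows for boundary fitting.

    Unlike the session stream (where attention performs a bounded walk), the
    calibration emitter sweeps the state space: attention is uniform over the
    retained values and meditation uniform within its admissible interval.
    Band columns: inlier rows draw regularized fractions below 0.6 of scale;
    ``outlier_fraction`` of rows draw all bands uniformly in (0.62, 1.0] of
    scale.  ``am_outlier_fraction`` of rows instead draw the pair uniformly
    outside the retained rectangles.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    values = cfg.level_table.valid_attention_values()
    rows = []
    for _ in range(n):
        if rng.random() < outlier_fraction:
            fracs = rng.uniform(0.62, 1.0, 8)
        else:
            fracs = _draw_band_fracs(rng, False)
        bands = tuple(int(f * s) for f, s in zip(fracs, cfg.band_scales))
        if rng.random() < am_outlier_fraction:
            while True:
                att = int(rng.integers(0, 101))
                med = int(rng.integers(0, 101))
                bounds = cfg.level_table.meditation_bounds(att)
                if bounds is None or not bounds[0] <= med <= bounds[1]:
                    break
        else:
            att = int(rng.choice(values))
            lo, hi = cfg.level_table.meditation_bounds(att)
            med = int(rng.integers(lo, hi + 1))
        rows.append(dict(zip(BAND_NAMES, bands), attention=att, meditation=med))
    return pd.DataFrame(rows, columns=list(BAND_NAMES) + ["attention", "meditation"])
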