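"""End-to-end attention optimization.

Each big packet runs through a fixed validation chain — checksum, cross-check
against the previous packet (the firmware never repeats an attention and
meditation pair in clean data), poor-signal gate, regularized band-power
bounds, attention-meditation boundary — then, if accepted, through deferred
blink correction, two-value smoothing, and seven-level classification.
Rejected packets still emit an output row carrying the rejection reason and
the held smoothed value, so consumers see an unbroken series with provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

from .blink import (
    BlinkConfig,
    BlinkDetector,
    BlinkState,
    Region,
    consume_pending,
    update,
)
from .boundaries import BoundaryState, check_am, is_wave_anomalous, regularize
from .levels import ATTENTION_CAP, DEFAULT_LEVEL_TABLE, LevelTable
from .protocol import BigPacket, SmallPacket

__all__ = [
    "REJECTION_REASONS",
    "ValidationResult",
    "AttentionOutput",
    "PipelineConfig",
    "validate",
    "apply_blink_correction",
    "smooth",
    "classify_level",
    "process",
]

REJECTION_REASONS = (
    "ok",
    "checksum",
    "cross_check",
    "poor_signal",
    "wave_bounds",
    "am_boundary",
    "null_region",
)


@dataclass(frozen=True)
class ValidationResult:
    accepted: bool
    reason: str

    def __post_init__(self):
        if self.reason not in REJECTION_REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if (self.reason == "ok") != self.accepted:
            raise ValueError("reason is 'ok' iff accepted")


OK = ValidationResult(True, "ok")


@dataclass(frozen=True)
class AttentionOutput:
    """One output row per big packet, accepted or not."""

    packet_index: int
    raw_attention: int
    corrected_attention: Optional[float]
    smoothed_attention: Optional[float]
    level: Optional[int]
    validation: ValidationResult


@dataclass
class PipelineConfig:
    """Run configuration: boundary state, blink feedback, smoothing policy.

    ``poor_signal_max`` is the highest tolerated poor-signal value (0 =
    strictest: any contact-quality complaint rejects).  ``smoothing`` is
    ``"mean"`` (two-value mean) or ``"ewma"`` (exponential, weight
    ``ewma_alpha`` on the new value).
    """

    boundary: BoundaryState = field(default_factory=BoundaryState)
    blink: BlinkConfig = field(default_factory=BlinkConfig)
    level_table: LevelTable = DEFAULT_LEVEL_TABLE
    blink_enabled: bool = True
    poor_signal_max: int = 0
    smoothing: str = "mean"
    ewma_alpha: float = 0.5
    clamp_max: float = float(ATTENTION_CAP)

    def __post_init__(self):
        if self.smoothing not in ("mean", "ewma"):
            raise ValueError("smoothing must be 'mean' or 'ewma'")


def validate(
    curr: BigPacket,
    prev: Optional[BigPacket],
    boundary: BoundaryState,
    poor_signal_max: int = 0,
) -> ValidationResult:
    """Run the fixed-order validation chain; the first failure wins."""
    if not curr.checksum_ok:
        return ValidationResult(False, "checksum")
    if (
        prev is not None
        and curr.attention == prev.attention
        and curr.meditation == prev.meditation
    ):
        return ValidationResult(False, "cross_check")
    if curr.poor_signal > poor_signal_max:
        return ValidationResult(False, "poor_signal")
    reg = regularize(curr.bands, boundary.scales)
    if is_wave_anomalous(reg, boundary.thresholds):
        return ValidationResult(False, "wave_bounds")
    if not check_am(curr.attention, curr.meditation, boundary.am_boundary):
        return ValidationResult(False, "am_boundary")
    return OK


def apply_blink_correction(
    raw_attention: int,
    prev_output: Optional[float],
    blink: BlinkState,
    cfg: BlinkConfig = BlinkConfig(),
    clamp_max: float = float(ATTENTION_CAP),
) -> float:
    """Deferred blink correction at the first big packet after a blink.

    Two additive terms: *dip stabilization* — if the drop from the previous
    output falls in the expected post-blink dip band, the base compensation
    pulls the value back up; *frequency bonus* — the pending region
    compensation, when the inter-blink interval fell in a valid region.
    With no blink pending this is the identity.  Output is clamped to
    [0, clamp_max] so compensation never enters the abandoned 98-100 band.
    """
    if blink.pending_compensation is None:
        return float(raw_attention)
    corrected = float(raw_attention)
    lo, hi = cfg.dip_band
    if prev_output is not None and lo <= prev_output - raw_attention <= hi:
        corrected += cfg.base_compensation
    if blink.region in (Region.NORMAL, Region.FOCUS, Region.HIGHLY_FOCUS):
        corrected += blink.pending_compensation
    return min(max(corrected, 0.0), clamp_max)


def smooth(
    prev_smoothed: Optional[float],
    corrected: float,
    mode: str = "mean",
    alpha: float = 0.5,
) -> float:
    """Two-value smoothing: the first value seeds, later values are averaged
    with the running output (or exponentially blended with ``mode='ewma'``)."""
    if prev_smoothed is None:
        return float(corrected)
    if mode == "ewma":
        return alpha * corrected + (1 - alpha) * prev_smoothed
    return 0.5 * (prev_smoothed + corrected)


def classify_level(attention: int, table: LevelTable = DEFAULT_LEVEL_TABLE) -> Optional[int]:
    """Level 1-7 for a retained attention value, None for rejected values.

    Abandoned intervals (0-4, 98-100) are discarded outright; null singletons
    and boundary bands never occur in clean firmware output, so their
    appearance is treated as a data error.
    """
    category, level = table.classify(attention)
    return level if category == "level" else None


def process(
    packets: Iterable[Union[SmallPacket, BigPacket]],
    config: Optional[PipelineConfig] = None,
) -> List[AttentionOutput]:
    """Run the full optimizer over an ordered packet sequence.

    Small packets feed the streaming blink detector (checksum-failed samples
    advance time but contribute no difference); each big packet yields one
    :class:`AttentionOutput`.  The reported level is the smoothed output
    snapped to the nearest retained attention value — corrected and smoothed
    values are algorithm-generated reals, so the strict null-value semantics
    of :func:`classify_level` apply only to the raw firmware integers.
    """
    cfg = config or PipelineConfig()
    detector = BlinkDetector(cfg.blink)
    blink_state = BlinkState()
    prev_big: Optional[BigPacket] = None
    prev_smoothed: Optional[float] = None
    outputs: List[AttentionOutput] = []
    big_index = 0
    for pkt in packets:
        if isinstance(pkt, SmallPacket):
            if cfg.blink_enabled:
                ev = detector.push(pkt.raw_value if pkt.checksum_ok else None)
                if ev is not None:
                    blink_state = update(blink_state, ev, cfg.blink)
            continue
        result = validate(pkt, prev_big, cfg.boundary, cfg.poor_signal_max)
        prev_big = pkt
        if result.accepted and classify_level(pkt.attention, cfg.level_table) is None:
            # raw attention in an abandoned/null interval: discard the value
            result = ValidationResult(False, "null_region")
        if not result.accepted:
            outputs.append(
                AttentionOutput(big_index, pkt.attention, None, prev_smoothed, None, result)
            )
        else:
            if cfg.blink_enabled:
                corrected = apply_blink_correction(
                    pkt.attention, prev_smoothed, blink_state, cfg.blink, cfg.clamp_max
                )
            else:
                corrected = float(pkt.attention)
            smoothed = smooth(prev_smoothed, corrected, cfg.smoothing, cfg.ewma_alpha)
            prev_smoothed = smoothed
            level = classify_level(cfg.level_table.nearest_valid(smoothed), cfg.level_table)
            outputs.append(
                AttentionOutput(big_index, pkt.attention, corrected, smoothed, level, result)
            )
        if cfg.blink_enabled:
            # the deferred-correction window closes with this big packet
            blink_state = consume_pending(blink_state)
        big_index += 1
    return outputs
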