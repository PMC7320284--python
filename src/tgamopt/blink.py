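"""Blink detection and frequency-based attention feedback.

Blinks dominate the single prefrontal electrode: each one produces a large
transient in the 2 ms raw-wave trace, with a consecutive-sample difference
well above the quiet-state range (quiet samples sit mostly within +/-350).
A first difference of 1000 or more marks a blink; the multi-sample excursion
of one physical blink is collapsed into a single event by a refractory
window.

The interval between the last two blinks (seconds per blink) is mapped to a
region and converted into an attention compensation, applied deferred at the
next big packet:

===============  ================  ==============================
interval (s)     region            compensation (attention points)
===============  ================  ==============================
< 2              invalid           none (dip stabilization only)
[2, 4.81)        normal            10
[4.81, 6.51)     focus             10 + interval x 0.8
[6.51, 8.33]     highly focus      10 + interval x 1.5
> 8.33           invalid           none (dip stabilization only)
===============  ================  ==============================
"""

from __future__ import annotations

import enum
from collections import deque
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

from .protocol import SMALL_PERIOD_S

__all__ = [
    "Region",
    "BlinkEvent",
    "BlinkState",
    "BlinkConfig",
    "BlinkDetector",
    "detect_blinks",
    "classify_interval",
    "compensation",
    "update",
    "consume_pending",
]


class Region(str, enum.Enum):
    INVALID_LOW = "invalid_low"
    NORMAL = "normal"
    FOCUS = "focus"
    HIGHLY_FOCUS = "highly_focus"
    INVALID_HIGH = "invalid_high"
    NONE = "none"


@dataclass
class BlinkEvent:
    """One detected blink: onset sample, onset time, and peak first-difference."""

    sample_index: int
    time_s: float
    peak_delta: int


@dataclass(frozen=True)
class BlinkConfig:
    """Detector and compensation parameters.

    ``delta_threshold`` is the consecutive-sample raw difference that fires a
    blink (ADC units); ``refractory_s`` collapses one physical blink's
    excursion into a single event; ``dip_band`` is the expected post-blink
    attention drop (points) that dip stabilization pulls back.
    ``mode='windowed'`` triggers on the max-min range of a short rolling
    window instead of the consecutive difference.
    """

    delta_threshold: int = 1000
    refractory_s: float = 0.4
    base_compensation: float = 10.0
    focus_slope: float = 0.8
    highly_slope: float = 1.5
    dip_band: Tuple[int, int] = (8, 20)
    sample_period_s: float = SMALL_PERIOD_S
    mode: str = "consecutive"
    window: int = 5

    def __post_init__(self):
        if self.delta_threshold <= 0:
            raise ValueError("delta_threshold must be positive")
        if self.focus_slope < 0 or self.highly_slope < 0:
            raise ValueError("slopes must be >= 0")
        if self.dip_band[0] > self.dip_band[1]:
            raise ValueError("dip_band must be ordered")
        if self.mode not in ("consecutive", "windowed"):
            raise ValueError("mode must be 'consecutive' or 'windowed'")


@dataclass(frozen=True)
class BlinkState:
    """Rolling state: last two blinks, their interval, region, and the
    compensation pending for the next big packet (None = no blink pending)."""

    events: Tuple[BlinkEvent, ...] = ()
    interval_s: Optional[float] = None
    region: Region = Region.NONE
    pending_compensation: Optional[float] = None


class BlinkDetector:
    """Streaming blink detector over a raw-sample feed.

    ``push`` returns a new :class:`BlinkEvent` at an excursion onset and
    ``None`` otherwise; threshold crossings within the refractory window of
    the previous crossing extend the current event (its ``peak_delta`` is
    updated in place).  ``push(None)`` advances time past an unusable sample
    and breaks the difference chain.
    """

    def __init__(self, cfg: BlinkConfig = BlinkConfig()):
        self.cfg = cfg
        self._i = -1
        self._prev: Optional[int] = None
        self._win: deque = deque(maxlen=cfg.window)
        self._last_cross_t: Optional[float] = None
        self._current: Optional[BlinkEvent] = None

    def _metric(self, value: int) -> Optional[int]:
        if self.cfg.mode == "consecutive":
            if self._prev is None:
                return None
            return abs(value - self._prev)
        self._win.append(value)
        if len(self._win) < self.cfg.window:
            return None
        return max(self._win) - min(self._win)

    def push(self, value: Optional[int]) -> Optional[BlinkEvent]:
        self._i += 1
        if value is None:
            self._prev = None
            self._win.clear()
            return None
        m = self._metric(value)
        if self.cfg.mode == "consecutive":
            self._prev = value
        if m is None or m < self.cfg.delta_threshold:
            return None
        t = self._i * self.cfg.sample_period_s
        if (
            self._last_cross_t is not None
            and self._current is not None
            and t - self._last_cross_t <= self.cfg.refractory_s
        ):
            self._last_cross_t = t
            self._current.peak_delta = max(self._current.peak_delta, m)
            return None
        self._last_cross_t = t
        self._current = BlinkEvent(self._i, t, m)
        return self._current


def detect_blinks(raw: Sequence[int], cfg: BlinkConfig = BlinkConfig()) -> List[BlinkEvent]:
    """Detect blink events in a raw trace (one sample per 2 ms by default)."""
    if len(raw) == 0:
        raise ValueError("raw trace must be non-empty")
    det = BlinkDetector(cfg)
    events: List[BlinkEvent] = []
    for x in raw:
        ev = det.push(int(x))
        if ev is not None:
            events.append(ev)
    return events


def classify_interval(interval_s: float) -> Region:
    """Map an inter-blink interval (seconds per blink) to its region."""
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    if interval_s < 2:
        return Region.INVALID_LOW
    if interval_s < 4.81:
        return Region.NORMAL
    if interval_s < 6.51:
        return Region.FOCUS
    if interval_s <= 8.33:
        return Region.HIGHLY_FOCUS
    return Region.INVALID_HIGH


def compensation(region: Region, interval_s: Optional[float], cfg: BlinkConfig = BlinkConfig()) -> float:
    """Attention points to add for a blink interval falling in ``region``.

    Invalid regions (and the no-interval state) earn no frequency bonus; dip
    stabilization still applies downstream.
    """
    if region in (Region.INVALID_LOW, Region.INVALID_HIGH, Region.NONE):
        return 0.0
    if interval_s is None or classify_interval(interval_s) is not region:
        raise ValueError(f"interval {interval_s} is not in region {region.value}")
    if region is Region.NORMAL:
        return cfg.base_compensation
    if region is Region.FOCUS:
        return cfg.base_compensation + interval_s * cfg.focus_slope
    return cfg.base_compensation + interval_s * cfg.highly_slope


def update(state: BlinkState, event: BlinkEvent, cfg: BlinkConfig = BlinkConfig()) -> BlinkState:
    """Fold a new blink event into the rolling state.

    The interval is the time difference of the last two blinks only; the
    resulting compensation is stored for the pipeline to consume at the next
    big packet.
    """
    if state.events and event.time_s < state.events[-1].time_s:
        raise ValueError("blink events must arrive in time order")
    events = (state.events + (event,))[-2:]
    if len(events) == 2:
        interval = events[1].time_s - events[0].time_s
        region = classify_interval(interval) if interval > 0 else Region.INVALID_LOW
    else:
        interval, region = None, Region.NONE
    return BlinkState(
        events=events,
        interval_s=interval,
        region=region,
        pending_compensation=compensation(region, interval, cfg),
    )


def consume_pending(state: BlinkState) -> BlinkState:
    """Clear the pending compensation once its big packet has passed."""
    return replace(state, pending_compensation=None)
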