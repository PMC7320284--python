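"""Seven-level attention classification table.

The TGAM firmware emits attention as a 0-100 integer, but empirically the
scale is sliced: many attention values never co-occur with any meditation
value (null singletons), narrow bands between levels act as boundaries, and
the extreme intervals 0-4 and 98-100 appear so rarely (and so erratically)
that they are abandoned outright.  Removing those gaps leaves 28 narrow
attention ranges that group into seven ordinal levels, each range with its
own admissible meditation interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "LevelRange",
    "LevelTable",
    "DEFAULT_LEVEL_TABLE",
    "ATTENTION_CAP",
]

#: top of the retained attention scale; 98-100 is abandoned
ATTENTION_CAP = 97


@dataclass(frozen=True)
class LevelRange:
    """One inclusive attention range with its meditation bounds."""

    level: int
    att_lo: int
    att_hi: int
    med_upper: int
    med_lower: int


# (level, att_lo, att_hi, meditation upper, meditation lower)
_RANGES = (
    (1, 7, 8, 74, 28),
    (1, 10, 11, 77, 26),
    (1, 13, 14, 83, 23),
    (1, 16, 17, 87, 19),
    (2, 20, 21, 90, 16),
    (2, 23, 24, 93, 14),
    (2, 26, 27, 97, 11),
    (2, 29, 30, 97, 10),
    (3, 34, 35, 97, 10),
    (3, 37, 38, 97, 13),
    (3, 40, 41, 94, 10),
    (3, 43, 44, 94, 10),
    (4, 47, 48, 91, 10),
    (4, 50, 51, 88, 10),
    (4, 53, 54, 88, 10),
    (4, 56, 57, 87, 10),
    (5, 60, 61, 84, 10),
    (5, 63, 64, 84, 10),
    (5, 66, 67, 81, 10),
    (5, 69, 70, 81, 16),
    (6, 74, 75, 78, 20),
    (6, 77, 78, 78, 20),
    (6, 80, 81, 75, 24),
    (6, 83, 84, 69, 27),
    (7, 87, 88, 69, 23),
    (7, 90, 91, 67, 27),
    (7, 93, 94, 64, 29),
    (7, 96, 97, 58, 33),
)

_NULL_SINGLETONS = frozenset(
    {9, 12, 15, 22, 25, 28, 36, 39, 42, 49, 52, 55, 62, 65, 68, 76, 79, 82, 89, 92, 95}
)
_BOUNDARY_BANDS = ((5, 6), (18, 19), (31, 33), (45, 46), (58, 59), (71, 73), (85, 86))
_ABANDONED = ((0, 4), (98, 100))


@dataclass(frozen=True)
class LevelTable:
    """Partition of the 0-100 attention scale into levels, nulls and gaps.

    ``classify`` returns a ``(category, level)`` pair where category is one of
    ``"level"`` (level 1-7), ``"null"`` (null singleton), ``"boundary"``
    (inter-level boundary band) or ``"abandoned"`` (0-4 / 98-100).
    """

    ranges: Tuple[LevelRange, ...] = tuple(LevelRange(*r) for r in _RANGES)
    null_singletons: frozenset = _NULL_SINGLETONS
    boundary_bands: Tuple[Tuple[int, int], ...] = _BOUNDARY_BANDS
    abandoned: Tuple[Tuple[int, int], ...] = _ABANDONED

    def classify(self, attention: int) -> Tuple[str, Optional[int]]:
        if not 0 <= attention <= 100:
            raise ValueError("attention must be in 0..100")
        for lo, hi in self.abandoned:
            if lo <= attention <= hi:
                return "abandoned", None
        if attention in self.null_singletons:
            return "null", None
        for lo, hi in self.boundary_bands:
            if lo <= attention <= hi:
                return "boundary", None
        for r in self.ranges:
            if r.att_lo <= attention <= r.att_hi:
                return "level", r.level
        raise AssertionError(f"attention {attention} not covered by the table")

    def meditation_bounds(self, attention: int) -> Optional[Tuple[int, int]]:
        """(lower, upper) admissible meditation for this attention, if retained."""
        for r in self.ranges:
            if r.att_lo <= attention <= r.att_hi:
                return r.med_lower, r.med_upper
        return None

    def valid_attention_values(self) -> Tuple[int, ...]:
        """All retained attention integers (levels 1-7), in increasing order."""
        vals = []
        for r in self.ranges:
            vals.extend(range(r.att_lo, r.att_hi + 1))
        return tuple(sorted(vals))

    def nearest_valid(self, x: float) -> int:
        """Nearest retained attention value; ties break toward the lower value."""
        vals = self.valid_attention_values()
        return min(vals, key=lambda v: (abs(v - x), v))


DEFAULT_LEVEL_TABLE = LevelTable()
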