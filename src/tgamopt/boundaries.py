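"""Band-power regularization and anomaly bounds.

The eight TGAM band powers are large, firmware-defined integers with no
physical unit, so they are *regularized* — divided by a per-band calibration
scale — before any rule is applied.  Two fitted structures then gate big
packets:

* per-band upper thresholds on the regularized values: a packet with three
  or more simultaneous exceedances is judged corrupted;
* an attention->meditation admissible band (lower/upper meditation per
  attention value): pairs outside it, or at attention values with no band at
  all, are judged corrupted.

Both structures are derived from calibration data with an Isolation Forest:
the threshold (or bound) is the extreme regularized value among points the
forest keeps as inliers.  The shipped defaults are the eight reference
thresholds (Delta 0.635, Theta 0.610, LowAlpha 0.640, HighAlpha 0.600,
LowBeta 0.615, HighBeta 0.605, LowGamma 0.620, MidGamma 0.630) and the
meditation columns of the seven-level classification table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.ensemble import IsolationForest

from .levels import DEFAULT_LEVEL_TABLE, LevelTable
from .protocol import BAND_NAMES

__all__ = [
    "BandScales",
    "BandThresholds",
    "AMBoundary",
    "ForestConfig",
    "BoundaryState",
    "DEFAULT_BAND_THRESHOLDS",
    "DEFAULT_BAND_SCALES",
    "default_am_boundary",
    "regularize",
    "count_exceedances",
    "is_wave_anomalous",
    "fit_band_thresholds",
    "fit_am_boundary",
    "check_am",
]

#: reference per-band upper thresholds on regularized band powers
_TABLE1 = (0.635, 0.610, 0.640, 0.600, 0.615, 0.605, 0.620, 0.630)

#: calibration divisors matching the bundled stream simulator's generative
#: scales (the divisors are device/session specific and are refit for real
#: hardware via :func:`fit_band_thresholds`)
_DEFAULT_SCALES = (
    1_500_000.0,
    600_000.0,
    300_000.0,
    250_000.0,
    200_000.0,
    150_000.0,
    90_000.0,
    60_000.0,
)


@dataclass(frozen=True)
class BandScales:
    """Per-band positive calibration divisors, keyed Delta..MidGamma."""

    scale: Tuple[float, ...] = _DEFAULT_SCALES

    def __post_init__(self):
        if len(self.scale) != 8 or any(s <= 0 for s in self.scale):
            raise ValueError("scale must be 8 positive values")


@dataclass(frozen=True)
class BandThresholds:
    """Per-band upper bounds on regularized band powers, each in (0, 1]."""

    threshold: Tuple[float, ...] = _TABLE1

    def __post_init__(self):
        if len(self.threshold) != 8 or any(not 0 < t <= 1 for t in self.threshold):
            raise ValueError("threshold must be 8 values in (0, 1]")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(BAND_NAMES, self.threshold))


DEFAULT_BAND_THRESHOLDS = BandThresholds()
DEFAULT_BAND_SCALES = BandScales()


@dataclass(frozen=True)
class ForestConfig:
    """Isolation Forest hyperparameters (defaults: 100 trees, subsample 256,
    contamination 0.05, fixed seed)."""

    n_trees: int = 100
    subsample_size: int = 256
    contamination: float = 0.05
    seed: int = 20200618

    def __post_init__(self):
        if self.n_trees <= 0 or self.subsample_size <= 0:
            raise ValueError("n_trees and subsample_size must be positive")
        if not 0 < self.contamination < 0.5:
            raise ValueError("contamination must be in (0, 0.5)")


class AMBoundary:
    """Admissible meditation interval per integer attention value.

    Attention values with no bucket are *null regions*: the firmware never
    emits them in clean data, so any pair observed there is rejected.
    """

    def __init__(self, buckets: Dict[int, Tuple[int, int]]):
        for a, (lo, hi) in buckets.items():
            if not 0 <= a <= 100:
                raise ValueError("attention bucket out of 0..100")
            if not (0 <= lo <= hi <= 100):
                raise ValueError(f"bad meditation bounds {lo}..{hi} at attention {a}")
        self.buckets = dict(sorted(buckets.items()))

    def lower(self, attention: int) -> Optional[int]:
        b = self.buckets.get(attention)
        return None if b is None else b[0]

    def upper(self, attention: int) -> Optional[int]:
        b = self.buckets.get(attention)
        return None if b is None else b[1]

    def __contains__(self, attention: int) -> bool:
        return attention in self.buckets

    def __eq__(self, other) -> bool:
        return isinstance(other, AMBoundary) and self.buckets == other.buckets

    def to_dict(self) -> Dict[str, list]:
        return {str(a): list(b) for a, b in self.buckets.items()}

    @classmethod
    def from_dict(cls, d: Dict[str, Sequence[int]]) -> "AMBoundary":
        return cls({int(a): (int(b[0]), int(b[1])) for a, b in d.items()})


def default_am_boundary(table: LevelTable = DEFAULT_LEVEL_TABLE) -> AMBoundary:
    """Boundary built from the classification table's meditation columns.

    The abandoned intervals (0-4, 98-100) receive permissive [0, 100] buckets:
    the firmware does emit those attention values, and their rejection is the
    classifier's job, not the meditation boundary's.
    """
    buckets: Dict[int, Tuple[int, int]] = {}
    for r in table.ranges:
        for a in range(r.att_lo, r.att_hi + 1):
            buckets[a] = (r.med_lower, r.med_upper)
    for lo, hi in table.abandoned:
        for a in range(lo, hi + 1):
            buckets[a] = (0, 100)
    return AMBoundary(buckets)


def regularize(bands: Sequence[float], scales: BandScales = DEFAULT_BAND_SCALES) -> np.ndarray:
    """Component-wise division of the 8 band powers by their calibration scales.

    Calibration-set values land in [0, 1]; fresh values may exceed 1 — the
    exceedance is the anomaly signal, so no clipping is applied.
    """
    arr = np.asarray(bands, dtype=float)
    if arr.shape != (8,):
        raise ValueError("bands must be an 8-vector")
    if np.any(arr < 0):
        raise ValueError("band powers must be non-negative")
    return arr / np.asarray(scales.scale, dtype=float)


def count_exceedances(
    reg: Sequence[float], thresholds: BandThresholds = DEFAULT_BAND_THRESHOLDS
) -> int:
    """Number of bands whose regularized value strictly exceeds its threshold."""
    arr = np.asarray(reg, dtype=float)
    if arr.shape != (8,):
        raise ValueError("reg must be an 8-vector")
    return int(np.sum(arr > np.asarray(thresholds.threshold)))


def is_wave_anomalous(
    reg: Sequence[float], thresholds: BandThresholds = DEFAULT_BAND_THRESHOLDS
) -> bool:
    """True iff three or more regularized bands exceed their upper bounds."""
    return count_exceedances(reg, thresholds) >= 3


def _forest(cfg: ForestConfig, n: int, seed_offset: int = 0) -> IsolationForest:
    return IsolationForest(
        n_estimators=cfg.n_trees,
        max_samples=min(cfg.subsample_size, n),
        contamination=cfg.contamination,
        random_state=(cfg.seed + seed_offset) % (2**31),
    )


def fit_band_thresholds(
    calibration: Sequence[Sequence[float]],
    cfg: ForestConfig = ForestConfig(),
    joint: bool = False,
) -> Tuple[BandScales, BandThresholds]:
    """Fit per-band scales and upper thresholds from a calibration set.

    Scales are the per-band calibration maxima (so regularized calibration
    data lies in [0, 1]); thresholds are, per band, the largest regularized
    value among points an Isolation Forest keeps as inliers at the configured
    contamination.  With ``joint=True`` a single forest is fitted on the
    8-vectors and inlier rows attribute the per-band maxima; by default one
    forest is fitted per band.
    """
    X = np.asarray(calibration, dtype=float)
    if X.ndim != 2 or X.shape[1] != 8:
        raise ValueError("calibration must be an (n, 8) array")
    if X.shape[0] < cfg.subsample_size:
        raise ValueError("calibration size must be >= subsample_size")
    if np.any(X < 0):
        raise ValueError("band powers must be non-negative")
    scales = X.max(axis=0)
    degenerate = np.array([np.unique(X[:, i]).size == 1 for i in range(8)])
    scales = np.where(scales <= 0, 1.0, scales)
    reg = X / scales
    thresholds = np.empty(8)
    if joint:
        pred = _forest(cfg, X.shape[0]).fit_predict(reg)
        inliers = reg[pred == 1]
        thresholds[:] = inliers.max(axis=0)
    else:
        for i in range(8):
            if degenerate[i]:
                continue
            col = reg[:, i : i + 1]
            pred = _forest(cfg, X.shape[0], seed_offset=i).fit_predict(col)
            thresholds[i] = col[pred == 1].max()
    if degenerate.any():
        names = [BAND_NAMES[i] for i in np.flatnonzero(degenerate)]
        warnings.warn(f"degenerate calibration band(s) {names}: threshold set to 1.0")
        thresholds[degenerate] = 1.0
    thresholds = np.clip(thresholds, np.finfo(float).tiny, 1.0)
    return BandScales(tuple(scales)), BandThresholds(tuple(thresholds))


def fit_am_boundary(
    pairs: Sequence[Tuple[int, int]], cfg: ForestConfig = ForestConfig()
) -> AMBoundary:
    """Fit the attention->meditation admissible band with an Isolation Forest.

    Inlier pairs define, per integer attention bucket, the min/max admissible
    meditation; buckets inside the covered attention span with no inliers
    inherit the nearest covered bucket's bounds.
    """
    P = np.asarray(pairs, dtype=float)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array of (attention, meditation)")
    atts = np.unique(P[:, 0])
    if atts.size < 2:
        raise ValueError("need at least 2 distinct attention values to fit")
    pred = _forest(cfg, P.shape[0]).fit_predict(P)
    inl = P[pred == 1]
    buckets: Dict[int, Tuple[int, int]] = {}
    for a in np.unique(inl[:, 0]).astype(int):
        med = inl[inl[:, 0] == a, 1]
        buckets[int(a)] = (int(med.min()), int(med.max()))
    covered = sorted(buckets)
    for a in range(covered[0], covered[-1] + 1):
        if a not in buckets:
            nearest = min(covered, key=lambda c: (abs(c - a), c))
            buckets[a] = buckets[nearest]
    return AMBoundary(buckets)


def check_am(attention: int, meditation: int, boundary: AMBoundary) -> bool:
    """True iff the pair lies inside the admissible meditation band.

    Attention values with no bucket (null regions) are always False.
    """
    if not (0 <= attention <= 100 and 0 <= meditation <= 100):
        raise ValueError("attention and meditation must be in 0..100")
    b = boundary.buckets.get(attention)
    return b is not None and b[0] <= meditation <= b[1]


@dataclass
class BoundaryState:
    """Everything the validation chain needs: scales, thresholds, A-M band."""

    scales: BandScales = field(default_factory=BandScales)
    thresholds: BandThresholds = field(default_factory=BandThresholds)
    am_boundary: AMBoundary = field(default_factory=default_am_boundary)
    forest: ForestConfig = field(default_factory=ForestConfig)

    def to_json(self, path: Union[str, Path]) -> None:
        doc = {
            "scales": list(self.scales.scale),
            "thresholds": list(self.thresholds.threshold),
            "am_boundary": self.am_boundary.to_dict(),
            "forest": asdict(self.forest),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "BoundaryState":
        doc = json.loads(Path(path).read_text())
        return cls(
            scales=BandScales(tuple(doc["scales"])),
            thresholds=BandThresholds(tuple(doc["thresholds"])),
            am_boundary=AMBoundary.from_dict(doc["am_boundary"]),
            forest=ForestConfig(**doc["forest"]),
        )
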