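"""Regularization, exceedance rules, Isolation-Forest fitting, A-M boundary."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tgamopt import (
    AMBoundary,
    BAND_NAMES,
    BandScales,
    BandThresholds,
    BoundaryState,
    DEFAULT_BAND_THRESHOLDS,
    DEFAULT_LEVEL_TABLE,
    ForestConfig,
    SimConfig,
    check_am,
    count_exceedances,
    default_am_boundary,
    emit_calibration_set,
    fit_am_boundary,
    fit_band_thresholds,
    is_wave_anomalous,
    regularize,
)

REFERENCE_THRESHOLDS = {
    "delta": 0.635,
    "theta": 0.610,
    "low_alpha": 0.640,
    "high_alpha": 0.600,
    "low_beta": 0.615,
    "high_beta": 0.605,
    "low_gamma": 0.620,
    "mid_gamma": 0.630,
}


def test_shipped_thresholds_reproduce_reference_table():
    assert DEFAULT_BAND_THRESHOLDS.as_dict() == REFERENCE_THRESHOLDS


def test_shipped_am_boundary_reproduces_meditation_columns():
    """Every retained attention range carries its table meditation bounds."""
    boundary = default_am_boundary()
    expected = {
        (7, 8): (28, 74), (10, 11): (26, 77), (13, 14): (23, 83), (16, 17): (19, 87),
        (20, 21): (16, 90), (23, 24): (14, 93), (26, 27): (11, 97), (29, 30): (10, 97),
        (34, 35): (10, 97), (37, 38): (13, 97), (40, 41): (10, 94), (43, 44): (10, 94),
        (47, 48): (10, 91), (50, 51): (10, 88), (53, 54): (10, 88), (56, 57): (10, 87),
        (60, 61): (10, 84), (63, 64): (10, 84), (66, 67): (10, 81), (69, 70): (16, 81),
        (74, 75): (20, 78), (77, 78): (20, 78), (80, 81): (24, 75), (83, 84): (27, 69),
        (87, 88): (23, 69), (90, 91): (27, 67), (93, 94): (29, 64), (96, 97): (33, 58),
    }
    for (lo, hi), (mlo, mhi) in expected.items():
        for a in range(lo, hi + 1):
            assert boundary.buckets[a] == (mlo, mhi)
    # null singletons and boundary bands have no bucket
    for a in (9, 22, 89, 95, 5, 18, 33, 45, 59, 71, 85):
        assert a not in boundary


def test_regularize_examples():
    scales = BandScales((10.0,) * 8)
    assert np.allclose(regularize([0] * 8, scales), 0.0)
    assert np.allclose(regularize([10] * 8, scales), 1.0)
    # a Delta power at 0.635x its scale sits exactly at its threshold
    reg = regularize([6.35] + [0] * 7, scales)
    assert reg[0] == pytest.approx(DEFAULT_BAND_THRESHOLDS.threshold[0])


def test_regularize_rejects_negative_bands():
    with pytest.raises(ValueError):
        regularize([-1] + [0] * 7, BandScales((1.0,) * 8))


@pytest.mark.parametrize(
    "bump,expected_count,expected_anomalous",
    [(0, 0, False), (2, 2, False), (3, 3, True), (8, 8, True)],
)
def test_exceedance_rule_fires_at_three(bump, expected_count, expected_anomalous):
    thr = np.array(DEFAULT_BAND_THRESHOLDS.threshold)
    reg = thr.copy()  # exactly at threshold: strict inequality, no exceedance
    reg[:bump] += 0.01
    assert count_exceedances(reg) == expected_count
    assert is_wave_anomalous(reg) is expected_anomalous


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(0, 1.5), min_size=8, max_size=8), st.integers(0, 7), st.floats(0, 0.5))
def test_exceedance_count_monotone_in_components(reg, idx, raise_by):
    base = count_exceedances(reg)
    raised = list(reg)
    raised[idx] += raise_by
    assert count_exceedances(raised) >= base


def test_fit_band_thresholds_recovers_generating_bound():
    """Calibration with 95% of regularized mass below ~0.6 and 5% outliers
    above recovers thresholds within +/-0.08 of 0.6 per band.

    The fit uses a contamination margin above the true outlier rate: the
    max-inlier extraction requires the cutoff to clear the outlier cluster.
    """
    cal = emit_calibration_set(SimConfig(seed=3), 4000, outlier_fraction=0.05)
    X = cal[list(BAND_NAMES)].to_numpy()
    scales, thr = fit_band_thresholds(X, ForestConfig(contamination=0.07))
    assert np.allclose(scales.scale, X.max(axis=0))
    for name, t in zip(BAND_NAMES, thr.threshold):
        assert abs(t - 0.6) <= 0.08, f"{name}: {t:.3f}"


def test_fit_band_thresholds_contamination_to_zero_limit():
    """With no outliers and vanishing contamination, thresholds approach the
    per-band regularized maxima (= 1 by construction of the scales)."""
    cal = emit_calibration_set(SimConfig(seed=4), 2000, outlier_fraction=0.0)
    _, thr = fit_band_thresholds(
        cal[list(BAND_NAMES)].to_numpy(), ForestConfig(contamination=1e-4)
    )
    assert all(t >= 0.999 for t in thr.threshold)


def test_fit_band_thresholds_deterministic_under_seed():
    cal = emit_calibration_set(SimConfig(seed=5), 1000, outlier_fraction=0.05)
    X = cal[list(BAND_NAMES)].to_numpy()
    a = fit_band_thresholds(X, ForestConfig(seed=99))
    b = fit_band_thresholds(X, ForestConfig(seed=99))
    assert a[1].threshold == b[1].threshold


def test_fit_band_thresholds_degenerate_band_warns():
    rng = np.random.default_rng(0)
    X = rng.uniform(10, 100, (500, 8))
    X[:, 2] = 7.0
    with pytest.warns(UserWarning, match="degenerate"):
        _, thr = fit_band_thresholds(X, ForestConfig(subsample_size=256))
    assert thr.threshold[2] == 1.0


def test_fit_band_thresholds_requires_enough_samples():
    with pytest.raises(ValueError):
        fit_band_thresholds(np.ones((10, 8)), ForestConfig(subsample_size=256))


def _rectangle_pairs(rng, n, outlier_fraction):
    table = DEFAULT_LEVEL_TABLE
    values = table.valid_attention_values()
    rows = []
    for _ in range(n):
        if rng.random() < outlier_fraction:
            while True:
                a, m = int(rng.integers(0, 101)), int(rng.integers(0, 101))
                b = table.meditation_bounds(a)
                if b is None or not b[0] <= m <= b[1]:
                    break
        else:
            a = int(rng.choice(values))
            lo, hi = table.meditation_bounds(a)
            m = int(rng.integers(lo, hi + 1))
        rows.append((a, m))
    return np.array(rows, float)


def test_fit_am_boundary_recovers_rectangle_edges():
    """Pairs uniform in the retained rectangles plus 5% noise outside recover
    the generating edges within +/-6 meditation units (rectangle resolution,
    >= 20 inliers); the reference row for attention 20-21 lands near (16, 90).
    """
    rng = np.random.default_rng(2)
    pairs = _rectangle_pairs(rng, 8000, 0.05)
    boundary = fit_am_boundary(pairs, ForestConfig(n_trees=200, subsample_size=2048))
    inl = {a: b for a, b in boundary.buckets.items()}
    for r in DEFAULT_LEVEL_TABLE.ranges:
        atts = [a for a in range(r.att_lo, r.att_hi + 1) if a in inl]
        assert atts, f"range {r.att_lo}-{r.att_hi} uncovered"
        lo = min(inl[a][0] for a in atts)
        hi = max(inl[a][1] for a in atts)
        n_range = int(np.sum((pairs[:, 0] >= r.att_lo) & (pairs[:, 0] <= r.att_hi)))
        if n_range >= 20:
            assert abs(lo - r.med_lower) <= 6, f"{r}: lower {lo}"
            assert abs(hi - r.med_upper) <= 6, f"{r}: upper {hi}"
    # worked row: attention 20-21 generated with meditation in [16, 90]
    assert abs(min(inl[20][0], inl[21][0]) - 16) <= 6
    assert abs(max(inl[20][1], inl[21][1]) - 90) <= 6


def test_fit_am_boundary_noiseless_grid_equals_edges():
    """On an exhaustive noiseless grid the fitted bounds sit on the rectangle
    edges (to within the one corner cell a nonzero contamination can trim)."""
    table = DEFAULT_LEVEL_TABLE
    pairs = []
    for r in table.ranges:
        for a in range(r.att_lo, r.att_hi + 1):
            for m in range(r.med_lower, r.med_upper + 1):
                pairs.append((a, m))
    pairs = np.array(pairs * 2, float)
    boundary = fit_am_boundary(pairs, ForestConfig(contamination=1e-4))
    for r in table.ranges:
        for a in range(r.att_lo, r.att_hi + 1):
            lo, hi = boundary.buckets[a]
            assert abs(lo - r.med_lower) <= 1
            assert abs(hi - r.med_upper) <= 1


def test_fit_am_boundary_needs_two_attention_values():
    with pytest.raises(ValueError):
        fit_am_boundary([(50, m) for m in range(30)])


def test_fitted_boundary_consistent_with_forest_labels():
    """check_am accepts every calibration point the forest kept as inlier.

    (The converse cannot hold at bucket resolution: gap buckets inherit
    neighbor bounds, so a flagged point there may still fall inside them.)
    """
    from sklearn.ensemble import IsolationForest

    rng = np.random.default_rng(9)
    pairs = _rectangle_pairs(rng, 3000, 0.05)
    cfg = ForestConfig()
    boundary = fit_am_boundary(pairs, cfg)
    pred = IsolationForest(
        n_estimators=cfg.n_trees,
        max_samples=min(cfg.subsample_size, len(pairs)),
        contamination=cfg.contamination,
        random_state=cfg.seed % (2**31),
    ).fit_predict(pairs)
    for (a, m), p in zip(pairs.astype(int), pred):
        if p == 1:
            assert check_am(a, m, boundary)


def test_check_am_worked_examples():
    boundary = default_am_boundary()
    assert check_am(87, 69, boundary) is True
    assert check_am(87, 100, boundary) is False
    for med in (0, 40, 100):
        assert check_am(89, med, boundary) is False  # null singleton


def test_boundary_state_json_roundtrip(tmp_path):
    state = BoundaryState()
    path = tmp_path / "model.json"
    state.to_json(path)
    loaded = BoundaryState.from_json(path)
    assert loaded.scales == state.scales
    assert loaded.thresholds == state.thresholds
    assert loaded.am_boundary == state.am_boundary
    assert loaded.forest == state.forest
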