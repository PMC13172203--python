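"""Feature-engine unit and property tests, each against an independent
oracle (closed form, hand computation, or brute-force enumeration)."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ggnfusion import radiomics as rx
from ggnfusion.radiomics import NoduleScan

AXIS_DIRECTIONS = ((1, 0, 0), (0, 1, 0), (0, 0, 1))


# ---------------------------------------------------------------------------
# volume / ESD / resampling


@pytest.mark.parametrize("n_vox,spacing,expected", [
    (100, (1, 1, 1), 100.0),
    (100, (0.5, 0.5, 2.0), 50.0),
])
def test_volume_is_count_times_voxel_volume(n_vox, spacing, expected):
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask.flat[:n_vox] = True
    assert rx.compute_volume(mask, spacing) == pytest.approx(expected)


def test_empty_mask_volume_warns_zero():
    with pytest.warns(RuntimeWarning):
        assert rx.compute_volume(np.zeros((3, 3, 3), bool), (1, 1, 1)) == 0.0


def test_sphere_phantom_volume_within_10pct(sphere_scan):
    v = rx.compute_volume(sphere_scan.mask, sphere_scan.spacing)
    assert v == pytest.approx(4 / 3 * math.pi * 125, rel=0.10)


@pytest.mark.parametrize("volume,expected", [
    (523.599, 10.0), (33.510, 4.0), (math.pi / 6, 1.0),
])
def test_esd_closed_form(volume, expected):
    assert rx.esd(volume) == pytest.approx(expected, abs=1e-3)


def test_esd_rejects_nonpositive():
    with pytest.raises(ValueError):
        rx.esd(0.0)


def test_resample_identity_when_already_isotropic(sphere_scan):
    out = rx.resample_isotropic(sphere_scan)
    np.testing.assert_array_equal(out.grid, sphere_scan.grid)
    np.testing.assert_array_equal(out.mask, sphere_scan.mask)


def test_resample_halfmm_cube_collapses_to_constant():
    grid = np.full((2, 2, 2), -500.0)
    scan = NoduleScan(grid, np.ones((2, 2, 2), bool), (0.5, 0.5, 0.5))
    out = rx.resample_isotropic(scan)
    assert out.grid.shape == (1, 1, 1)
    assert out.grid[0, 0, 0] == pytest.approx(-500.0)
    assert out.spacing == (1.0, 1.0, 1.0)


def test_resample_conserves_sphere_volume_within_15pct():
    spacing = (0.7, 0.7, 1.25)
    shape = (31, 31, 19)
    c = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape).astype(float)
    r2 = sum(((idx[k] - c[k]) * spacing[k]) ** 2 for k in range(3))
    mask = r2 <= 25.0
    scan = NoduleScan(np.where(mask, -600.0, -1000.0), mask, spacing)
    before = rx.compute_volume(scan.mask, scan.spacing)
    out = rx.resample_isotropic(scan)
    after = rx.compute_volume(out.mask, out.spacing)
    assert after == pytest.approx(before, rel=0.15)


# ---------------------------------------------------------------------------
# discretisation and first order


def test_discretise_anchor_and_edges():
    assert rx.discretise([-1024.0])[0] == 1
    # bin 1 spans [-1024, -999); -999 opens bin 2
    assert rx.discretise([-1000.0])[0] == 1
    assert rx.discretise([-999.0])[0] == 2
    assert rx.discretise([-1024.0])[0] != rx.discretise([-999.0])[0]
    assert len(np.unique(rx.discretise(np.full(50, -650.0)))) == 1


@given(st.lists(st.floats(-1024, 1000), min_size=2, max_size=30),
       st.floats(-1024, 1000))
def test_discretise_monotone(values, extra):
    b = rx.discretise(sorted(values + [extra]))
    assert np.all(np.diff(b) >= 0)


def test_first_order_hand_values():
    f = rx.first_order_features([-700.0, -650.0, -600.0])
    assert f["firstorder.mean"] == pytest.approx(-650.0)
    assert f["firstorder.variance"] == pytest.approx(1666.6667, abs=0.01)


def test_first_order_constant_roi():
    f = rx.first_order_features(np.full(20, -500.0))
    assert f["firstorder.variance"] == 0.0
    assert f["firstorder.entropy"] == 0.0
    assert math.isnan(f["firstorder.skewness"])
    assert math.isnan(f["firstorder.kurtosis"])


def test_entropy_two_equal_mass_bins_is_one_bit():
    vals = np.r_[np.full(10, -1000.0), np.full(10, -900.0)]
    assert rx.first_order_features(vals)["firstorder.entropy"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# texture


def _brute_glcm(bins, mask, directions):
    """Pair-enumeration oracle for the direction-merged symmetric GLCM."""
    from collections import Counter

    pairs = Counter()
    shape = bins.shape
    for x in np.argwhere(mask):
        for d in directions:
            nb = x + np.array(d)
            if all(0 <= nb[k] < shape[k] for k in range(3)) and mask[tuple(nb)]:
                a, b = bins[tuple(x)], bins[tuple(nb)]
                pairs[(a, b)] += 1
                pairs[(b, a)] += 1
    return pairs


def test_glcm_constant_roi_trivials():
    bins = np.ones((3, 3, 3), dtype=int)
    mask = np.ones((3, 3, 3), bool)
    f = rx.glcm_features(bins, mask)
    assert f["glcm.contrast"] == 0.0
    assert f["glcm.idm"] == 1.0
    assert f["glcm.joint_entropy"] == 0.0


def test_glcm_checkerboard_contrast_one_along_axes():
    idx = np.indices((4, 4, 4)).sum(axis=0)
    bins = 1 + (idx % 2)
    mask = np.ones((4, 4, 4), bool)
    f = rx.glcm_features(bins, mask, directions=AXIS_DIRECTIONS)
    assert f["glcm.contrast"] == pytest.approx(1.0)


def test_glcm_matches_pair_enumeration_oracle():
    rng = np.random.default_rng(5)
    bins = rng.integers(1, 4, size=(4, 4, 3))
    mask = rng.random((4, 4, 3)) < 0.8
    mask.flat[:2] = True
    pairs = _brute_glcm(bins, mask, rx.UNIT_DIRECTIONS_3D)
    total = sum(pairs.values())
    contrast = sum(c * (a - b) ** 2 for (a, b), c in pairs.items()) / total
    f = rx.glcm_features(bins, mask)
    assert f["glcm.contrast"] == pytest.approx(contrast, abs=1e-12)


def test_glrlm_single_run_line():
    bins = np.ones((1, 1, 6), dtype=int)
    mask = np.ones((1, 1, 6), bool)
    f = rx.glrlm_features(bins, mask, directions=((0, 0, 1),))
    assert f["glrlm.run_percentage"] == pytest.approx(1 / 6)
    assert f["glrlm.sre"] == pytest.approx(1 / 36)
    assert f["glrlm.lre"] == pytest.approx(36.0)


def test_glrlm_alternating_bins_sre_one():
    bins = (1 + np.arange(6) % 2).reshape(1, 1, 6)
    mask = np.ones((1, 1, 6), bool)
    f = rx.glrlm_features(bins.astype(int), mask)
    assert f["glrlm.sre"] == pytest.approx(1.0)
    assert f["glrlm.lre"] == pytest.approx(1.0)


def test_glrlm_constant_roi_maximises_lre():
    """Among all bin assignments on the same 1x1x4 support, the constant one
    has the largest long-run emphasis (brute force over assignments)."""
    mask = np.ones((1, 1, 4), bool)
    best = -np.inf
    const_lre = None
    from itertools import product

    for assign in product((1, 2), repeat=4):
        bins = np.array(assign).reshape(1, 1, 4)
        lre = rx.glrlm_features(bins, mask)["glrlm.lre"]
        best = max(best, lre)
        if len(set(assign)) == 1:
            const_lre = lre
    assert const_lre == pytest.approx(best)


def test_texture_invariant_under_axis_rotation():
    rng = np.random.default_rng(3)
    bins = rng.integers(1, 5, size=(4, 4, 4))
    mask = rng.random((4, 4, 4)) < 0.7
    mask.flat[:3] = True
    base_glcm = rx.glcm_features(bins, mask)
    base_glrlm = rx.glrlm_features(bins, mask)
    for axes in ((0, 1), (0, 2), (1, 2)):
        rb = np.rot90(bins, k=1, axes=axes)
        rm = np.rot90(mask, k=1, axes=axes)
        for key, val in rx.glcm_features(rb, rm).items():
            assert val == pytest.approx(base_glcm[key], abs=1e-10)
        for key, val in rx.glrlm_features(rb, rm).items():
            assert val == pytest.approx(base_glrlm[key], abs=1e-10)


# ---------------------------------------------------------------------------
# LoG filter


def test_log_filter_constant_and_linearity():
    const = np.full((9, 9, 9), -400.0)
    resp = rx.log_filter(const, 1.5)
    assert np.allclose(resp[2:-2, 2:-2, 2:-2], 0.0, atol=1e-8)
    rng = np.random.default_rng(0)
    img = rng.normal(size=(7, 7, 7))
    np.testing.assert_allclose(rx.log_filter(2 * img, 1.0),
                               2 * rx.log_filter(img, 1.0), atol=1e-10)


def test_log_filter_gaussian_blob_extremal_at_centre():
    shape = (15, 15, 15)
    c = (np.array(shape) - 1) / 2.0
    idx = np.indices(shape).astype(float)
    r2 = sum((idx[k] - c[k]) ** 2 for k in range(3))
    blob = np.exp(-r2 / (2 * 2.0**2))
    resp = rx.log_filter(blob, 2.0)
    assert np.unravel_index(np.argmin(resp), shape) == tuple(c.astype(int))


def test_log_filter_rejects_bad_sigma():
    with pytest.raises(ValueError):
        rx.log_filter(np.zeros((3, 3, 3)), 0.0)


# ---------------------------------------------------------------------------
# growth / delta


def test_growth_metrics_closed_forms():
    gm = rx.growth_metrics(100.0, 200.0, 365.0)
    assert gm.vdt == pytest.approx(365.0)
    assert gm.annualised_rate == pytest.approx(100.0 / 365.0 * 365.25, abs=0.01)
    gm2 = rx.growth_metrics(100.0, 50.0, 365.0)
    assert gm2.vdt == pytest.approx(-365.0)
    gm3 = rx.growth_metrics(100.0, 100.0, 1000.0)
    assert gm3.daily_rate == 0.0
    assert gm3.vdt_undefined and math.isnan(gm3.vdt)


def test_growth_metrics_validation():
    with pytest.raises(ValueError):
        rx.growth_metrics(0.0, 100.0, 100.0)
    with pytest.raises(ValueError):
        rx.growth_metrics(100.0, -1.0, 100.0)


def test_delta_features_arithmetic_and_sign():
    f0 = {"a": 10.0, "b": 1.0}
    f1 = {"a": 12.0, "b": 0.5}
    d = rx.delta_features(f0, f1, 100.0)
    assert d["a"] == pytest.approx(0.02)
    assert d["b"] == pytest.approx(-0.005)
    assert rx.delta_features(f0, f0, 10.0) == {"a": 0.0, "b": 0.0}
    with pytest.raises(ValueError):
        rx.delta_features(f0, {"a": 1.0}, 10.0)


@given(st.floats(-50, 50), st.floats(-50, 50))
def test_log1p_rates_monotone_and_odd(x, y):
    tx = rx.log1p_rates({"delta.f": x})["delta.f"]
    ty = rx.log1p_rates({"delta.f": y})["delta.f"]
    if x < y:
        assert tx < ty
    assert rx.log1p_rates({"delta.f": -x})["delta.f"] == pytest.approx(-tx, abs=1e-12)


def test_log1p_rates_fixed_points():
    assert rx.log1p_rates({"rate.x": 0.0})["rate.x"] == 0.0
    assert rx.log1p_rates({"rate.x": math.e - 1})["rate.x"] == pytest.approx(1.0)
    assert rx.log1p_rates({"shape.x": 5.0})["shape.x"] == 5.0  # not a rate


# ---------------------------------------------------------------------------
# full extraction


def test_extract_features_finite_and_hu_invariant_shape(sphere_scan):
    feats = rx.extract_features(sphere_scan)
    finite = {k: v for k, v in feats.items()
              if not k.startswith(("glcm.correlation", "firstorder.skew",
                                   "firstorder.kurt", "log_"))}
    for k, v in finite.items():
        assert np.isfinite(v), k
    shifted = NoduleScan(sphere_scan.grid + 200.0, sphere_scan.mask, sphere_scan.spacing)
    feats2 = rx.extract_features(shifted)
    for k in feats:
        if k.startswith("shape."):
            assert feats2[k] == pytest.approx(feats[k])
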