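"""Segmentation metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.distance import cdist

from conftest import sphere_mask
from la_recon.evaluation import (
    CorrelationResult,
    EvalReport,
    coverage,
    coverage_correlation,
    dice_score,
    error_map,
    la_diameter,
    la_volume,
    sensitivity_specificity,
    stsd,
)
from la_recon.types import LAGeometry, surface_voxels


def brute_stsd(a, b):
    """O(n^2) all-pairs nearest-surface-distance oracle."""
    sa = np.argwhere(surface_voxels(a))
    sb = np.argwhere(surface_voxels(b))
    d = cdist(sa, sb)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sa) + len(sb))


def brute_diameter(mask, spacing, ap_axis):
    best = 0
    slice_axis = [a for a in range(3) if a != ap_axis][0]
    ap_in_slice = ap_axis - 1 if ap_axis > slice_axis else ap_axis
    for i in range(mask.shape[slice_axis]):
        sl = np.take(mask, i, axis=slice_axis)
        rows = sl.sum(axis=ap_in_slice)  # sum along the A-P axis
        best = max(best, int(rows.max()) if rows.size else 0)
    return best * spacing


# -- dice ----------------------------------------------------------------------
def test_dice_hand_values():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    a.ravel()[:5] = True
    b.ravel()[5:10] = True  # disjoint, 5 voxels each
    assert dice_score(a, b) == pytest.approx(1 / 11)
    assert dice_score(a, a) == 1.0
    c = np.zeros((4, 4, 4), bool)
    d = np.zeros((4, 4, 4), bool)
    c.ravel()[:10] = True
    d.ravel()[5:15] = True  # 10 each, 5 shared
    assert dice_score(c, d) == pytest.approx(11 / 21)
    assert dice_score(c, d) == dice_score(d, c)


# -- stsd ----------------------------------------------------------------------
def test_stsd_identity_and_concentric_spheres():
    s = sphere_mask((41, 41, 41), (20, 20, 20), 10.0)
    assert stsd(s, s) == 0.0
    gap = 5.0
    outer = sphere_mask((41, 41, 41), (20, 20, 20), 15.0)
    assert stsd(s, outer) == pytest.approx(gap, abs=1.0)


def test_stsd_matches_brute_force(small_mask_pairs):
    for a, b in small_mask_pairs[:30]:
        assert stsd(a, b) == pytest.approx(brute_stsd(a, b), abs=1e-9)


def test_stsd_empty_mask_raises():
    a = np.zeros((5, 5, 5), bool)
    b = np.ones((5, 5, 5), bool)
    with pytest.raises(ValueError, match="non-empty"):
        stsd(a, b)


# -- sensitivity / specificity -------------------------------------------------
def test_confusion_metrics():
    truth = np.zeros((10, 10), bool).reshape(10, 10)
    truth = np.zeros((100,), bool)
    truth[:10] = True
    pred = np.zeros((100,), bool)
    pred[:8] = True  # 8 TP, 2 FN
    pred[10:15] = True  # 5 FP -> 85 TN
    truth3, pred3 = truth.reshape(4, 5, 5), pred.reshape(4, 5, 5)
    sens, spec = sensitivity_specificity(pred3, truth3)
    assert sens == pytest.approx(0.8)
    assert spec == pytest.approx(85 / 90)
    assert sensitivity_specificity(truth3, truth3) == (1.0, 1.0)
    all_fg = np.ones_like(truth3)
    sens, spec = sensitivity_specificity(all_fg, truth3)
    assert (sens, spec) == (1.0, 0.0)
    # undefined sensitivity on all-negative truth
    sens, _ = sensitivity_specificity(pred3, np.zeros_like(truth3))
    assert np.isnan(sens)


def test_erosion_monotonicity():
    truth = sphere_mask((31, 31, 31), (15, 15, 15), 9.0)
    pred = sphere_mask((31, 31, 31), (15, 15, 15), 10.0)
    eroded = ndimage.binary_erosion(pred, iterations=2)
    s0, sp0 = sensitivity_specificity(pred, truth)
    s1, sp1 = sensitivity_specificity(eroded, truth)
    assert s1 < s0
    assert sp1 >= sp0


# -- diameter / volume ---------------------------------------------------------
def test_diameter_sphere_and_single_voxel():
    mask = sphere_mask((45, 45, 45), (22, 22, 22), 20.0)
    assert la_diameter(mask, 0.625) == pytest.approx(40 * 0.625, abs=2 * 0.625)
    single = np.zeros((5, 5, 5), bool)
    single[2, 2, 2] = True
    assert la_diameter(single, 0.7) == pytest.approx(0.7)
    assert la_diameter(np.zeros((5, 5, 5), bool), 1.0) == 0.0


def test_diameter_matches_brute_force(small_mask_pairs):
    for a, _ in small_mask_pairs[:40]:
        assert la_diameter(a, 1.0, ap_axis=1) == pytest.approx(brute_diameter(a, 1.0, 1))


def test_volume_arithmetic_and_ellipsoid():
    assert la_volume(np.zeros((3, 3, 3), bool), 1.0) == 0.0
    cube = np.zeros((12, 12, 12), bool)
    cube[:10, :10, :10] = True
    assert la_volume(cube, 0.625) == pytest.approx(1000 * 0.625**3 / 1000.0)
    g = np.meshgrid(*[np.arange(s, dtype=float) for s in (61, 51, 41)], indexing="ij", sparse=True)
    ell = ((g[0] - 30) / 25) ** 2 + ((g[1] - 25) / 20) ** 2 + ((g[2] - 20) / 15) ** 2 <= 1
    assert la_volume(ell, 1.0) == pytest.approx(4 / 3 * np.pi * 25 * 20 * 15 / 1000, rel=0.05)


# -- coverage ------------------------------------------------------------------
def test_coverage_limits(desk_la):
    surf_world = desk_la.voxel_to_world(np.argwhere(surface_voxels(desk_la.mask)))
    assert coverage(surf_world, desk_la) == 1.0
    assert coverage(np.empty((0, 3)), desk_la) == 0.0


def test_coverage_empty_surface_raises():
    la = LAGeometry(mask=np.zeros((4, 4, 4), bool), spacing_mm=1.0)
    with pytest.raises(ValueError, match="surface"):
        coverage(np.zeros((4, 3)), la)


# -- error maps ----------------------------------------------------------------
def test_error_map_consistency():
    a = sphere_mask((35, 35, 35), (17, 17, 17), 9.0)
    b = sphere_mask((35, 35, 35), (17, 17, 17), 13.0)
    em = error_map(a, b)
    assert em.mean_symmetric == pytest.approx(stsd(a, b), abs=1e-12)
    vals = em.pred_to_truth[em.pred_surface]
    assert vals.mean() == pytest.approx(4.0, abs=1.0)  # concentric gap
    em_same = error_map(a, a)
    assert not em_same.pred_to_truth.any()


# -- correlation ---------------------------------------------------------------
def _report(cov, dice):
    return EvalReport(
        dice=dice, stsd_px=1 - dice, sensitivity=dice, specificity=0.99,
        diameter_mm=40.0, volume_cm3=50.0, diameter_error_pct=5.0,
        volume_error_pct=5.0, coverage=cov,
    )


def test_pearson_exact_linear_cases():
    covs = [0.2, 0.25, 0.3, 0.35, 0.4]
    res = coverage_correlation([_report(c, 0.5 + c) for c in covs])
    assert res["dice"].r == pytest.approx(1.0)
    assert res["stsd_px"].r == pytest.approx(-1.0)
    # zero-variance metric flagged, not raised
    assert res["diameter_error_pct"].degenerate


def test_pearson_matches_textbook_formula():
    cov = np.array([0.19, 0.25, 0.28, 0.33, 0.40])
    dice = np.array([0.81, 0.86, 0.84, 0.90, 0.93])
    res = coverage_correlation([_report(c, d) for c, d in zip(cov, dice)])["dice"]
    x, y = cov - cov.mean(), dice - dice.mean()
    r_manual = (x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum())
    assert res.r == pytest.approx(r_manual, abs=1e-12)
    assert isinstance(res, CorrelationResult)


def test_correlation_requires_three_reports():
    with pytest.raises(ValueError, match=">= 3"):
        coverage_correlation([_report(0.2, 0.8)])
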