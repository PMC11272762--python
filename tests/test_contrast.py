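"""IEC-phantom ROI placement, contrast recovery, background variability,
lung error."""

import numpy as np
import pytest

from spectqc import contrast as con
from spectqc import phantom_sim as sim
from spectqc.datatypes import AnalysisError

from conftest import spheres_from_truth


def test_roi_area_close_to_analytic(iec_noiseless):
    vol, truth = iec_noiseless
    roi = con.CircleRoi((0.0, 0.0), 37.0, 24)
    n = con._roi_mask(vol, roi).sum()
    area = n * vol.voxel_mm[0] * vol.voxel_mm[1]
    assert area == pytest.approx(np.pi * 18.5 ** 2, rel=0.05)


def test_slice_offsets_snap_to_grid(iec_noiseless):
    vol, truth = iec_noiseless
    rois = con.place_rois(vol, spheres_from_truth(truth),
                          wall_radius_mm=truth["wall_radius_mm"])
    assert sorted(np.round(rois.slice_offsets_mm, 2)) == \
        [-19.68, -9.84, 0.0, 9.84, 19.68]
    for dia, lst in rois.background_rois.items():
        assert len(lst) == 60


def test_full_recovery_limit(iec_noiseless):
    """Noiseless, unblurred phantom: every Q = 100 % and N = 0."""
    vol, truth = iec_noiseless
    out = con.analyze_contrast(vol, spheres_from_truth(truth), 8.0,
                               wall_radius_mm=truth["wall_radius_mm"])
    for c in out["contrast"]:
        q = c.get("Q_H_percent", c.get("Q_C_percent"))
        assert q == pytest.approx(100.0, abs=1e-9)
    for v in out["background_variability"].values():
        assert v["N_percent"] == pytest.approx(0.0, abs=1e-9)
    assert out["lung_error"]["summary_percent"] == pytest.approx(0.0)


def test_partial_recovery_inverts_contrast_formula(iec_noiseless):
    """Fill at 5.466x background but analyze against the 8:1 nominal
    ratio: Q_H = (5.466-1)/(8-1) = 63.8 %."""
    _, truth = iec_noiseless
    vol, _ = sim.gen_iec_volume(sphere_to_background_ratio=5.466,
                                noiseless=True)
    out = con.analyze_contrast(vol, spheres_from_truth(truth), 8.0,
                               wall_radius_mm=truth["wall_radius_mm"])
    for c in out["contrast"]:
        if c["hot"]:
            assert c["Q_H_percent"] == pytest.approx(63.8, abs=1e-9)


def test_cold_contrast_endpoints(iec_noiseless):
    vol, truth = iec_noiseless
    spheres = spheres_from_truth(truth)
    rois = con.place_rois(vol, spheres,
                          wall_radius_mm=truth["wall_radius_mm"])
    bg = con.background_variability(vol, rois)
    # cold spheres hold zero counts -> Q_C = 100 %
    for c in con.contrast_recovery(vol, rois, 8.0, bg):
        if not c["hot"]:
            assert c["Q_C_percent"] == pytest.approx(100.0)
    # fill the cold spheres to the background level -> Q_C = 0 %
    filled = vol.counts.copy()
    for sp, roi in rois.sphere_rois:
        if not sp.hot:
            mask = con._roi_mask(vol, roi)
            filled[:, :, roi.slice_index][mask] = truth["background_level"]
    vol2 = type(vol)(filled, vol.voxel_mm)
    for c in con.contrast_recovery(vol2, rois, 8.0, bg):
        if not c["hot"]:
            assert c["Q_C_percent"] == pytest.approx(0.0, abs=1e-9)


def test_background_variability_hand_value(iec_noiseless):
    """ROI means alternating 99/101 over K=60 -> SD = sqrt(60/59),
    N = 1.0084 %."""
    vol, truth = iec_noiseless
    rois = con.place_rois(vol, spheres_from_truth(truth),
                          wall_radius_mm=truth["wall_radius_mm"])
    counts = vol.counts.copy()
    for k, roi in enumerate(rois.background_rois[37.0]):
        mask = con._roi_mask(vol, roi)
        counts[:, :, roi.slice_index][mask] = 99.0 if k % 2 == 0 else 101.0
    vol2 = type(vol)(counts, vol.voxel_mm)
    bg = con.background_variability(vol2, rois)[37.0]
    assert bg["c_B"] == pytest.approx(100.0)
    assert bg["SD"] == pytest.approx(np.sqrt(60.0 / 59.0), rel=1e-9)
    assert bg["N_percent"] == pytest.approx(1.0084, abs=1e-3)


def test_lung_error_endpoints_and_ratio(iec_noiseless):
    vol, truth = iec_noiseless
    rois = con.place_rois(vol, spheres_from_truth(truth),
                          wall_radius_mm=truth["wall_radius_mm"])
    bg = con.background_variability(vol, rois)
    # foam insert holds zero counts -> 0 %
    assert con.lung_error(vol, rois, bg)["summary_percent"] == \
        pytest.approx(0.0)
    # set the lung ROI content to a known fraction of background
    for frac, expected in ((1.0, 100.0), (0.458, 45.8)):
        counts = vol.counts.copy()
        level = frac * truth["background_level"]
        for roi in rois.lung_rois:
            mask = con._roi_mask(vol, roi)
            counts[:, :, roi.slice_index][mask] = level
        vol2 = type(vol)(counts, vol.voxel_mm)
        out = con.lung_error(vol2, rois, bg)
        assert out["summary_percent"] == pytest.approx(expected, abs=1e-9)
        for v in out["per_slice_percent"]:
            assert v == pytest.approx(expected, abs=1e-9)


def test_contrast_scale_invariance(iec_noiseless):
    vol, truth = iec_noiseless
    spheres = spheres_from_truth(truth)
    wall = truth["wall_radius_mm"]
    vol_scaled = type(vol)(vol.counts * 7.3, vol.voxel_mm)
    a = con.analyze_contrast(vol, spheres, 8.0, wall_radius_mm=wall)
    b = con.analyze_contrast(vol_scaled, spheres, 8.0, wall_radius_mm=wall)
    for ca, cb in zip(a["contrast"], b["contrast"]):
        qa = ca.get("Q_H_percent", ca.get("Q_C_percent"))
        qb = cb.get("Q_H_percent", cb.get("Q_C_percent"))
        assert qb == pytest.approx(qa, rel=1e-12)


def test_background_variability_scales_with_counts(iec_noiseless):
    """N_j ~ 1/sqrt(counts): log-log slope -0.5 +/- 0.15 over 3 levels."""
    _, truth = iec_noiseless
    spheres = spheres_from_truth(truth)
    levels = np.array([50.0, 200.0, 800.0])
    ns = []
    for lvl in levels:
        vol, _ = sim.gen_iec_volume(sphere_to_background_ratio=8.0,
                                    background_level=lvl, seed=3)
        rois = con.place_rois(vol, spheres,
                              wall_radius_mm=truth["wall_radius_mm"])
        ns.append(con.background_variability(vol, rois)[37.0]["N_percent"])
    slope = np.polyfit(np.log(levels), np.log(ns), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.15)


def test_placement_fails_in_cramped_phantom(iec_noiseless):
    vol, truth = iec_noiseless
    with pytest.raises(AnalysisError):
        con.place_rois(vol, spheres_from_truth(truth), wall_radius_mm=95.0)
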