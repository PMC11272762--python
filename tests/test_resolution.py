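"""Planar LSF widths, distance extrapolation, SPECT orthogonal-view
resolution reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectqc import PlanarImage
from spectqc import phantom_sim as sim
from spectqc import resolution as res
from spectqc.datatypes import FWHM_PER_SIGMA, InputError


def _bound(voxel_mm, true_fwhm):
    """Discretization error bound used across the width tests."""
    return voxel_mm ** 2 / (2.0 * true_fwhm)


# -- extrapolation ----------------------------------------------------------

def test_extrapolation_matches_printed_values():
    assert res.extrapolate_resolution(9.91, 150, 100, 17.72) == \
        pytest.approx(6.96, abs=0.005)
    assert res.extrapolate_resolution(18.67, 150, 100, 17.72) == \
        pytest.approx(13.10, abs=0.005)


def test_extrapolation_identity_at_same_distance():
    assert res.extrapolate_resolution(9.91, 150, 150, 17.72) == 9.91


@settings(deadline=None, max_examples=50)
@given(r=st.floats(0.5, 30.0), scale=st.floats(0.1, 10.0),
       l1=st.floats(0.0, 50.0), l2=st.floats(0.0, 50.0))
def test_extrapolation_linear_and_monotone_in_leff(r, scale, l1, l2):
    # linear in the measured resolution
    a = res.extrapolate_resolution(r, 150, 100, l1)
    b = res.extrapolate_resolution(r * scale, 150, 100, l1)
    assert b == pytest.approx(a * scale, rel=1e-12)
    # for target < measured the ratio (target+l)/(measured+l) grows with
    # l, so the extrapolated value increases toward the measured one
    lo, hi = sorted((l1, l2))
    assert res.extrapolate_resolution(r, 150, 100, hi) >= \
        res.extrapolate_resolution(r, 150, 100, lo) - 1e-12
    assert res.extrapolate_resolution(r, 150, 100, hi) <= r + 1e-12


# -- 1-D profile widths -----------------------------------------------------

def test_triangle_profile_half_width():
    prof = res.Profile(np.arange(9) * 1.0,
                       np.array([0, 1, 2, 3, 4, 3, 2, 1, 0], dtype=float))
    assert res.profile_width(prof, 0.5) == pytest.approx(4.0)


def test_gaussian_fwtm_ratio():
    x = np.arange(-40, 40.5, 0.5)
    y = np.exp(-0.5 * (x / 3.0) ** 2)
    prof = res.Profile(x, y)
    fwhm = res.profile_width(prof, 0.5)
    fwtm = res.profile_width(prof, 0.1)
    assert fwtm / fwhm == pytest.approx(1.8226, rel=0.01)


# -- planar LSF -------------------------------------------------------------

def test_planar_line_recovery_within_bound():
    img, truth = sim.gen_line_image(fwhm_mm=9.91, total_counts=1e7,
                                    noiseless=True)
    rep = res.planar_resolution_report([img])
    fwhm = rep.per_detector[0]["fwhm_measured_mm"]
    assert abs(fwhm - 9.91) <= _bound(2.46, 9.91)


def test_pedestal_subtraction_leaves_width_unchanged():
    img, _ = sim.gen_line_image(fwhm_mm=9.91, total_counts=1e7,
                                noiseless=True)
    with_bg = PlanarImage(img.counts + 5.0, img.pixel_pitch_mm)
    w0 = res.profile_width(res.lsf_from_planar(img), 0.5)
    w1 = res.profile_width(res.lsf_from_planar(with_bg), 0.5)
    assert w1 == pytest.approx(w0, rel=0.02)


def test_tilted_line_rejected():
    # a gently tilted line (2 deg) passes; a 10 deg tilt is rejected.
    # the grid is tall enough that the drifting centre stays in-bounds
    pitch = 2.46
    cols = 112
    rows = 80
    x = (np.arange(rows) + 0.5) * pitch

    def make(tilt_deg):
        slope = np.tan(np.deg2rad(tilt_deg))
        img = np.zeros((rows, cols))
        for c in range(cols):
            center = 40 * pitch + slope * (c + 0.5 - cols / 2) * pitch
            img[:, c] = np.exp(-0.5 * ((x - center) / 3.0) ** 2)
        return PlanarImage(img, (pitch, pitch))

    res.lsf_from_planar(make(2.0))      # fine
    with pytest.raises(InputError):
        res.lsf_from_planar(make(10.0))


# -- SPECT views ------------------------------------------------------------

def test_single_isotropic_source_views_agree():
    vol, truth = sim.gen_point_volume([[0, 0, 0]], 6.0, 2.46, 1e6,
                                      grid_shape=(64, 64, 64),
                                      noiseless=True)
    (sv,) = res.spect_point_views(vol, truth["source_positions_mm"])
    assert sv.is_central
    assert np.allclose(sv.transverse, sv.coronal)
    assert np.allclose(sv.transverse, sv.sagittal)


def test_three_point_layout_labels_and_recovery():
    vol, truth = sim.gen_point_volume([[0, 0, 0], [75, 0, 0], [-75, 0, 0]],
                                      6.0, 2.46, 1e6, noiseless=True)
    views = res.spect_point_views(vol, truth["source_positions_mm"])
    assert sum(v.is_central for v in views) == 1
    rep = res.spect_resolution_report(views, vol, "three_point_air")
    tol = _bound(2.46, 6.0)
    for key in ("central_transaxial_mm", "central_axial_mm",
                "peripheral_radial_mm", "peripheral_tangential_mm",
                "peripheral_axial_mm"):
        assert abs(rep[key]["average"] - 6.0) <= tol, key


def test_rotation_swaps_radial_tangential_labels_only():
    kw = dict(fwhm_mm=6.0, voxel_mm=2.46, counts_per_source=1e6,
              noiseless=True)
    vol_x, t_x = sim.gen_point_volume([[0, 0, 0], [75, 0, 0], [-75, 0, 0]], **kw)
    vol_y, t_y = sim.gen_point_volume([[0, 0, 0], [0, 75, 0], [0, -75, 0]], **kw)
    rep_x = res.spect_resolution_report(
        res.spect_point_views(vol_x, t_x["source_positions_mm"]), vol_x)
    rep_y = res.spect_resolution_report(
        res.spect_point_views(vol_y, t_y["source_positions_mm"]), vol_y)
    assert rep_x["peripheral_radial_mm"]["average"] == pytest.approx(
        rep_y["peripheral_radial_mm"]["average"], rel=1e-9)
    assert rep_x["peripheral_tangential_mm"]["average"] == pytest.approx(
        rep_y["peripheral_tangential_mm"]["average"], rel=1e-9)


def test_anisotropic_marginals_match_per_axis_truth():
    true = (3.4, 2.9, 2.8)
    vol, truth = sim.gen_point_volume([[0, 0, 0]], true, 1.23, 1e6,
                                      grid_shape=(96, 96, 96),
                                      noiseless=True)
    (sv,) = res.spect_point_views(vol, truth["source_positions_mm"])
    widths = res._axis_widths(sv, vol)
    assert abs(widths["x_transverse"] - 3.4) <= _bound(1.23, 3.4)
    assert abs(widths["y_transverse"] - 2.9) <= _bound(1.23, 2.9)
    assert abs(widths["z_coronal"] - 2.8) <= _bound(1.23, 2.8)


def test_voxel_refinement_convergence_is_monotone():
    errors = []
    for voxel, n in ((4.92, 32), (2.46, 64), (1.23, 128)):
        vol, truth = sim.gen_point_volume([[0, 0, 0]], 10.0, voxel, 1e6,
                                          grid_shape=(n, n, n),
                                          noiseless=True)
        (sv,) = res.spect_point_views(vol, truth["source_positions_mm"])
        w = res._axis_widths(sv, vol)
        errors.append(abs(w["x_transverse"] - 10.0))
    assert errors[0] > errors[1] > errors[2]


def test_overlapping_slabs_rejected():
    vol, _ = sim.gen_point_volume([[0, 0, 0]], 6.0, 2.46, 1e6,
                                  grid_shape=(64, 64, 64), noiseless=True)
    with pytest.raises(InputError):
        res.spect_point_views(vol, [[0, 0, 0], [5, 0, 0]])


def test_central_only_reports_flag():
    vol, truth = sim.gen_point_volume([[0, 0, 0]], 6.0, 2.46, 1e6,
                                      grid_shape=(64, 64, 64),
                                      noiseless=True)
    views = res.spect_point_views(vol, truth["source_positions_mm"])
    rep = res.spect_resolution_report(views, vol, "three_point_air")
    assert "no_peripheral_sources" in rep["flags"]
    assert "peripheral_radial_mm" not in rep


def test_triple_line_layout_recovery():
    vol, truth = sim.gen_line_volume([[0, 0], [75, 0], [-75, 0]], 6.0, 2.46,
                                     1e6, noiseless=True)
    rep = res.spect_resolution_report(
        None, vol, "triple_line_scatter",
        line_positions_mm=truth["line_positions_mm"])
    tol = _bound(2.46, 6.0)
    for key in ("central_mm", "radial_mm", "tangential_mm"):
        assert abs(rep[key]["average"] - 6.0) <= tol, key
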