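"""Photopeak location and FWHM estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectqc import Spectrum
from spectqc import phantom_sim as sim
from spectqc import spectrometry as sp
from spectqc.datatypes import AnalysisError, FWHM_PER_SIGMA, InputError


def _spectrum(counts, channel_keV=0.5, start_keV=100.0, isotope="Tc99m"):
    counts = np.asarray(counts, dtype=float)
    edges = start_keV + channel_keV * np.arange(counts.size + 1)
    return Spectrum(edges, counts, isotope=isotope)


def test_symmetric_parabola_vertex_at_center():
    s = _spectrum([0, 0, 1, 3, 4, 3, 1, 0, 0])
    fit = sp.parabolic_peak(s.channel_centers, s.counts, min_significance=0)
    assert fit.position == pytest.approx(s.channel_centers[4])
    assert fit.height == pytest.approx(4.0)


def test_plateau_tie_breaks_low_and_flags():
    s = _spectrum([0, 2, 4, 4, 2, 0, 0])
    fit = sp.parabolic_peak(s.channel_centers, s.counts, min_significance=0)
    assert fit.index == 2
    assert "plateau_tie" in fit.flags


def test_vertex_matches_dense_grid_argmax():
    # oracle: the continuous Gaussian's argmax is the generator peak energy
    spec, _ = sim.gen_spectrum(140.5, 3.0 * FWHM_PER_SIGMA / 140.5, 1e6,
                               0.5, 0.0, noiseless=True)
    fit = sp.find_photopeak(spec, sp.default_window(140.5))
    assert abs(fit.position - 140.5) < 0.05


def test_flat_window_raises():
    s = _spectrum(np.full(20, 100.0))
    with pytest.raises(AnalysisError):
        sp.parabolic_peak(s.channel_centers, s.counts)


def test_triangle_fwhm_exact():
    s = _spectrum([0, 1, 2, 3, 4, 3, 2, 1, 0])
    fit = sp.parabolic_peak(s.channel_centers, s.counts, min_significance=0)
    width = sp.interpolated_width(s.channel_centers, s.counts, fit, 0.5)
    assert width == pytest.approx(2.0)   # 4 channels of 0.5 keV


@pytest.mark.parametrize("sigma", [1.0, 2.0, 3.0, 5.0])
def test_gaussian_fwhm_within_discretization_bound(sigma):
    """|estimate - true| <= h^2 / (2 * true FWHM) on noiseless Gaussians."""
    true_fwhm = FWHM_PER_SIGMA * sigma
    spec, _ = sim.gen_spectrum(140.5, true_fwhm / 140.5, 1e6, 0.5, 0.0,
                               noiseless=True)
    fit = sp.find_photopeak(spec, sp.default_window(140.5))
    fwhm = sp.fwhm_by_interpolation(spec, fit)
    assert abs(fwhm - true_fwhm) <= 0.5 ** 2 / (2.0 * true_fwhm)


def test_fwtm_close_to_gaussian_tenth_width():
    # closed form: tenth-max width = 1.8226 x FWHM = 4.2919 keV for sigma=1;
    # 0.5 keV channels bias the linear interpolation high by ~2 %
    spec, _ = sim.gen_spectrum(140.5, FWHM_PER_SIGMA / 140.5, 1e6, 0.5, 0.0,
                               noiseless=True)
    fit = sp.find_photopeak(spec, sp.default_window(140.5))
    fwtm = sp.fwhm_by_interpolation(spec, fit, fraction=0.1)
    assert fwtm == pytest.approx(4.2919, rel=0.025)


def test_width_undefined_when_tail_never_drops():
    s = _spectrum([5, 5, 6, 9, 6, 5, 5])
    fit = sp.parabolic_peak(s.channel_centers, s.counts, min_significance=0)
    with pytest.raises(AnalysisError):
        sp.interpolated_width(s.channel_centers, s.counts, fit, 0.1)


@settings(deadline=None, max_examples=25)
@given(scale=st.floats(min_value=0.1, max_value=100.0))
def test_scale_equivariance(scale):
    spec, _ = sim.gen_spectrum(140.5, 0.06, 1e5, 0.5, 0.02, seed=11)
    scaled = Spectrum(spec.channel_edges, spec.counts * scale,
                      isotope=spec.isotope)
    win = sp.default_window(140.5)
    f0 = sp.find_photopeak(spec, win)
    f1 = sp.find_photopeak(scaled, win)
    assert f1.position == pytest.approx(f0.position, rel=1e-12)
    w0 = sp.fwhm_by_interpolation(spec, f0)
    w1 = sp.fwhm_by_interpolation(scaled, f1)
    assert w1 == pytest.approx(w0, rel=1e-9)


@pytest.mark.parametrize("k_shift", [-20, -5, 5, 20])
def test_energy_shift_equivariance(k_shift):
    spec, _ = sim.gen_spectrum(140.5, 0.06, 1e5, 0.5, 0.02, seed=12)
    shifted = Spectrum(spec.channel_edges + k_shift * spec.channel_keV,
                       spec.counts, isotope=spec.isotope)
    f0 = sp.find_photopeak(spec, sp.default_window(140.5))
    shift_keV = k_shift * spec.channel_keV
    f1 = sp.find_photopeak(shifted, sp.default_window(140.5 + shift_keV))
    assert f1.position - f0.position == pytest.approx(shift_keV, abs=1e-9)
    assert sp.fwhm_by_interpolation(shifted, f1) == pytest.approx(
        sp.fwhm_by_interpolation(spec, f0), abs=1e-9)


def test_mixed_isotopes_rejected():
    a, _ = sim.gen_spectrum(140.5, 0.05, 1e4, seed=1, isotope="Tc99m")
    b, _ = sim.gen_spectrum(140.5, 0.05, 1e4, seed=2, isotope="I123")
    with pytest.raises(InputError):
        sp.energy_resolution([a, b])


def test_single_spectrum_average_collapses():
    s, _ = sim.gen_spectrum(122.0, 0.0602, 1e6, 0.5, 0.02, seed=3,
                            isotope="Co57")
    res = sp.energy_resolution([s], nominal_peak_keV=122.0)
    lo, hi = res.resolution_range_percent
    assert lo == hi == res.resolution_percent


@pytest.mark.parametrize("peak,frac,expected", [
    (140.5, 0.0527, 5.27),   # Tc-99m
    (122.0, 0.0602, 6.02),   # Co-57
])
def test_fleet_average_recovers_true_resolution(peak, frac, expected):
    spectra = [sim.gen_spectrum(peak, frac, 4.5e6, 0.5, 0.02, seed=s)[0]
               for s in range(1, 7)]
    res = sp.energy_resolution(spectra, nominal_peak_keV=peak)
    assert res.resolution_percent == pytest.approx(expected, abs=0.05)
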