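"""Generator-level guarantees: reproducibility, noiseless totals,
ground-truth round-trips, and the count-rate response-model invariants."""

import numpy as np
import pytest

from spectqc import GroundTruth, T_HALF_TC99M_S
from spectqc import phantom_sim as sim
from spectqc.datatypes import InputError, mean_lifetime


def _gen_by_name(name, seed, noiseless=False):
    if name == "spectrum":
        return sim.gen_spectrum(140.5, 0.0527, 1e5, 0.5, 0.02, seed=seed,
                                noiseless=noiseless)[0].counts
    if name == "flood":
        return sim.gen_flood(total_counts=1e5, seed=seed,
                             noiseless=noiseless)[0].counts
    if name == "line":
        return sim.gen_line_image(fwhm_mm=9.91, total_counts=1e5, seed=seed,
                                  noiseless=noiseless)[0].counts
    if name == "points":
        return sim.gen_point_volume([[0.0, 0.0, 0.0]], 6.0, 2.46, 1e5,
                                    grid_shape=(32, 32, 32), seed=seed,
                                    noiseless=noiseless)[0].counts
    if name == "iec":
        return sim.gen_iec_volume(background_level=5.0,
                                  grid_shape=(128, 128, 5), seed=seed,
                                  noiseless=noiseless)[0].counts
    if name == "cylinder":
        imgs, _ = sim.gen_cylinder_projections(3, [0.8, 0.9, 1.0], seed=seed,
                                               noiseless=noiseless)
        return np.stack([im.counts for im in imgs])
    raise AssertionError(name)


ALL_GENS = ["spectrum", "flood", "line", "points", "iec", "cylinder"]


@pytest.mark.parametrize("name", ALL_GENS)
def test_same_seed_bit_identical(name):
    a = _gen_by_name(name, seed=42)
    b = _gen_by_name(name, seed=42)
    assert np.array_equal(a, b)


@pytest.mark.parametrize("name", ALL_GENS)
def test_different_seed_differs(name):
    a = _gen_by_name(name, seed=1)
    b = _gen_by_name(name, seed=2)
    assert not np.array_equal(a, b)


def test_noiseless_totals_match_request():
    spec, _ = sim.gen_spectrum(140.5, 0.05, 4.5e6, 0.5, 0.02, noiseless=True)
    assert spec.counts.sum() == pytest.approx(4.5e6, rel=1e-3)
    img, _ = sim.gen_flood(total_counts=2e7, noiseless=True)
    assert img.counts.sum() == pytest.approx(2e7, rel=1e-3)
    line, _ = sim.gen_line_image(total_counts=1e7, noiseless=True)
    assert line.counts.sum() == pytest.approx(1e7, rel=1e-3)
    vol, _ = sim.gen_point_volume([[0, 0, 0]], 6.0, 2.46, 1e6,
                                  grid_shape=(48, 48, 48), noiseless=True)
    assert vol.counts.sum() == pytest.approx(1e6, rel=1e-3)


def test_ground_truth_roundtrip():
    _, truth = sim.gen_flood(total_counts=1e4, seed=7, noiseless=True)
    back = GroundTruth.from_json(truth.to_json())
    assert back["total_counts"] == truth["total_counts"]
    assert np.array_equal(np.asarray(back["gain_map"]),
                          np.asarray(truth["gain_map"]))


# -- response models --------------------------------------------------------

@pytest.mark.parametrize("model", [
    sim.ResponseModel("identity"),
    sim.ResponseModel("saturating_exponential", {"ocr_max": 760e3, "k": 272.9e3}),
    sim.ResponseModel("nonparalyzable", {"dead_time_s": 1e-6}),
    sim.ResponseModel("paralyzable", {"dead_time_s": 1e-6}),
    sim.ResponseModel("clamped_linear", {"ocr_max": 100.0}),
])
def test_response_invariants(model):
    x = np.logspace(0, 7, 200)
    y = model(x)
    assert model(0.0) == 0.0
    assert np.all(y <= x + 1e-9)
    if model.model_kind in ("saturating_exponential", "clamped_linear",
                            "identity"):
        assert np.all(np.diff(y) >= -1e-9)


def test_solve_saturating_shape_hits_loss_point():
    k = sim.solve_saturating_shape(760e3, 917e3, 0.2)
    model = sim.ResponseModel("saturating_exponential",
                              {"ocr_max": 760e3, "k": k})
    assert model(917e3) == pytest.approx(0.8 * 917e3, rel=1e-12)


def test_decay_series_identity_closed_form():
    series, truth = sim.gen_decay_series(
        100.0, T_HALF_TC99M_S, sim.ResponseModel("identity"),
        cps_per_MBq=10.0, schedule=[(0, 10), (100, 10), (200, 20)],
        noiseless=True)
    tau = mean_lifetime(T_HALF_TC99M_S)
    r0 = 1000.0
    for p in series.points:
        expected = tau * r0 * (np.exp(-p.t_start_s / tau)
                               - np.exp(-(p.t_start_s + p.dt_s) / tau))
        assert p.counts == pytest.approx(expected, rel=1e-12)


def test_background_only_series():
    series, _ = sim.gen_decay_series(
        0.0, T_HALF_TC99M_S, sim.ResponseModel("identity"),
        cps_per_MBq=10.0, background_cps=50.0,
        schedule=[(0, 10), (100, 10), (200, 10)], noiseless=True)
    for p in series.points:
        assert p.counts == pytest.approx(50.0 * p.dt_s)


def test_quadrature_matches_closed_form_for_linear_response():
    """A lossless response expressed as a 'nonlinear' model must integrate
    to the identity closed form (quadrature correctness check)."""
    huge_cap = sim.ResponseModel("clamped_linear", {"ocr_max": 1e12})
    sched = [(0, 10), (1000, 60)]
    a, _ = sim.gen_decay_series(100.0, T_HALF_TC99M_S, huge_cap, 10.0,
                                schedule=sched, noiseless=True)
    b, _ = sim.gen_decay_series(100.0, T_HALF_TC99M_S,
                                sim.ResponseModel("identity"), 10.0,
                                schedule=sched, noiseless=True)
    for pa, pb in zip(a.points, b.points):
        assert pa.counts == pytest.approx(pb.counts, rel=1e-7)


# -- guards -----------------------------------------------------------------

def test_spectrum_input_guards():
    with pytest.raises(InputError):
        sim.gen_spectrum(300.0, 0.05, 1e5)          # outside energy range
    with pytest.raises(InputError):
        sim.gen_spectrum(140.5, 0.05, 0.0)          # no counts
    with pytest.raises(InputError):
        sim.gen_spectrum(140.5, 1.5, 1e5)           # absurd width


def test_flood_gain_shape_guard():
    with pytest.raises(InputError):
        sim.gen_flood(gain_map=np.ones((4, 4)))


def test_line_sampling_warning_recorded():
    _, truth = sim.gen_line_image(fwhm_mm=3.0, total_counts=1e4,
                                  noiseless=True)
    assert not truth["sampling_adequate"]
    assert "warning" in truth


def test_point_overlap_rejected():
    with pytest.raises(InputError):
        sim.gen_point_volume([[0, 0, 0], [10, 0, 0]], 6.0, 2.46, 1e5,
                             grid_shape=(64, 64, 64))


def test_iec_geometry_guards():
    bad = sim.IECPhantomSpec(sphere_diameters_mm=(120.0, 120.0),
                             hot_flags=(True, False))
    with pytest.raises(InputError):
        sim.gen_iec_volume(bad, grid_shape=(64, 64, 9))
    with pytest.raises(InputError):
        sim.gen_cylinder_projections(3, [0.5, 0.5])   # wrong factor count


def test_channel_refinement_convergence_is_monotone():
    """Noiseless recovery error shrinks as the channel width shrinks."""
    from spectqc import spectrometry
    true_fwhm = 140.5 * 0.0527
    errors = []
    for ch in (2.0, 1.0, 0.5):
        spec, _ = sim.gen_spectrum(140.5, 0.0527, 1e6, ch, 0.0,
                                   noiseless=True)
        res = spectrometry.energy_resolution([spec], nominal_peak_keV=140.5)
        errors.append(abs(res.fwhm_keV - true_fwhm))
    assert errors[0] > errors[1] > errors[2]
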