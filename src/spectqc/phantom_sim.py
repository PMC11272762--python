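"""Synthetic phantom and detector data with known ground truth.

Every generator takes an explicit integer seed, records the parameters it
drew from in a :class:`GroundTruth`, and supports a ``noiseless`` mode in
which the expected (Poisson-mean) image is returned directly so that any
downstream estimation error is attributable purely to discretization.

What is emulated: Gaussian photopeaks on a low flat background, Poisson
counting noise, per-pixel gain non-uniformity with defective pixels, a
saturating detector count-rate response, Gaussian PSF-blurred line/point
sources, and the IEC body-phantom sphere/lung/background geometry. What is
not: Compton continua, scatter and attenuation physics, and projection/
reconstruction — volumes are generated directly in reconstructed space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import integrate, optimize, stats

from .datatypes import (
    FWHM_PER_SIGMA,
    CountRatePoint,
    CountRateSeries,
    DetectorGeometry,
    GroundTruth,
    InputError,
    PlanarImage,
    Spectrum,
    T_HALF_TC99M_S,
    VolumeImage,
    mean_lifetime,
    rng_from_seed,
)

__all__ = [
    "ResponseModel",
    "solve_saturating_shape",
    "gen_spectrum",
    "gen_flood",
    "decay_schedule",
    "gen_decay_series",
    "gen_line_image",
    "gen_point_volume",
    "gen_line_volume",
    "gen_iec_volume",
    "gen_cylinder_projections",
    "gen_sensitivity_counts",
    "IECPhantomSpec",
]

ENERGY_RANGE_KEV = (40.0, 279.0)


# ---------------------------------------------------------------------------
# Detector count-rate response models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResponseModel:
    """Observed-vs-input count-rate transfer function OCR = f(ICR).

    Supported kinds:

    ``identity``
        lossless, OCR = ICR.
    ``saturating_exponential``
        ``min(ICR, ocr_max * (1 - exp(-ICR/k)))`` — lossless at low rate,
        plateauing at ``ocr_max``. The clamp to the bisector keeps
        OCR <= ICR everywhere (the raw exponential would overshoot the
        bisector at low rate for plateau-matched parameters); the result
        is a constructed readout surface rather than a physical dead-time
        model, passing exactly through a stated plateau and loss point.
    ``nonparalyzable``
        ``ICR / (1 + ICR * dead_time_s)``.
    ``paralyzable``
        ``ICR * exp(-ICR * dead_time_s)``.
    ``clamped_linear``
        ``min(ICR, ocr_max)``.
    """

    model_kind: str = "identity"
    parameters: dict = field(default_factory=dict)

    def __call__(self, icr: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(icr, dtype=float)
        if np.any(x < 0):
            raise InputError("input rate must be non-negative")
        p = self.parameters
        if self.model_kind == "identity":
            out = x
        elif self.model_kind == "saturating_exponential":
            ocr_max, k = p["ocr_max"], p["k"]
            out = np.minimum(x, ocr_max * (-np.expm1(-x / k)))
        elif self.model_kind == "nonparalyzable":
            out = x / (1.0 + x * p["dead_time_s"])
        elif self.model_kind == "paralyzable":
            out = x * np.exp(-x * p["dead_time_s"])
        elif self.model_kind == "clamped_linear":
            out = np.minimum(x, p["ocr_max"])
        else:
            raise InputError(f"unknown response model {self.model_kind!r}")
        return out if np.ndim(icr) else float(out)


def solve_saturating_shape(ocr_max_cps: float, icr_at_loss_cps: float,
                           loss_fraction: float = 0.2) -> float:
    """Shape constant ``k`` of the saturating-exponential response such
    that the observed rate equals ``(1 - loss_fraction) * icr_at_loss_cps``
    at input rate ``icr_at_loss_cps``.

    Solves ``ocr_max * (1 - exp(-ICR/k)) = (1-loss) * ICR`` for k.
    """
    target = (1.0 - loss_fraction) * icr_at_loss_cps
    if not 0 < target < ocr_max_cps:
        raise InputError("loss point must lie below the plateau")
    ratio = target / ocr_max_cps
    # 1 - exp(-ICR/k) = ratio  =>  k = -ICR / ln(1 - ratio)
    return -icr_at_loss_cps / math.log1p(-ratio)


# ---------------------------------------------------------------------------
# Energy spectra
# ---------------------------------------------------------------------------

def gen_spectrum(peak_keV: float, fwhm_fraction: float, total_counts: float,
                 channel_keV: float = 0.5, background_fraction: float = 0.0,
                 seed: int | None = None, noiseless: bool = False,
                 isotope: str = "", detector_id: str = "",
                 ) -> tuple[Spectrum, GroundTruth]:
    """Gaussian photopeak on a flat background, channelized and
    Poisson-sampled.

    The photopeak carries ``(1 - background_fraction)`` of
    ``total_counts`` with sigma = ``fwhm_fraction * peak_keV / 2.3548``;
    the background is flat over the full 40-279 keV acquisition range.
    """
    if not 0.0 < fwhm_fraction < 1.0:
        raise InputError("fwhm_fraction must be in (0, 1)")
    if total_counts <= 0:
        raise InputError("total_counts must be positive")
    if not ENERGY_RANGE_KEV[0] <= peak_keV <= ENERGY_RANGE_KEV[1]:
        raise InputError(
            f"peak {peak_keV} keV outside acquisition range {ENERGY_RANGE_KEV}")
    if channel_keV <= 0:
        raise InputError("channel width must be positive")
    if not 0.0 <= background_fraction < 1.0:
        raise InputError("background_fraction must be in [0, 1)")

    lo, hi = ENERGY_RANGE_KEV
    n_chan = int(round((hi - lo) / channel_keV))
    edges = lo + channel_keV * np.arange(n_chan + 1)
    sigma = fwhm_fraction * peak_keV / FWHM_PER_SIGMA
    # expected counts per channel: Gaussian integral + flat background
    cdf = stats.norm.cdf(edges, loc=peak_keV, scale=sigma)
    peak_part = (cdf[1:] - cdf[:-1]) / (cdf[-1] - cdf[0])
    expected = total_counts * ((1.0 - background_fraction) * peak_part
                               + background_fraction / n_chan)
    if noiseless:
        counts = expected
    else:
        counts = rng_from_seed(seed).poisson(expected).astype(float)
    truth = GroundTruth({
        "peak_keV": peak_keV,
        "fwhm_fraction": fwhm_fraction,
        "fwhm_keV": fwhm_fraction * peak_keV,
        "sigma_keV": sigma,
        "total_counts": float(total_counts),
        "background_fraction": background_fraction,
        "channel_keV": channel_keV,
        "seed": seed,
        "noiseless": noiseless,
    })
    spec = Spectrum(edges, counts, isotope=isotope, detector_id=detector_id)
    return spec, truth


# ---------------------------------------------------------------------------
# Flood fields
# ---------------------------------------------------------------------------

def gen_flood(geometry: DetectorGeometry | None = None,
              gain_map: np.ndarray | None = None,
              defect_mask: np.ndarray | None = None,
              total_counts: float = 20e6,
              seed: int | None = None, noiseless: bool = False,
              detector_id: str = "", duration_s: float = 0.0,
              ) -> tuple[PlanarImage, GroundTruth]:
    """Flood-field exposure of one detector column.

    Expected per-pixel counts are proportional to the gain map (1.0 =
    nominal response, 0 = dead pixel); the expected total equals
    ``total_counts`` exactly. ``defect_mask`` marks the pixels whose gain
    was deliberately made defective, for recovery bookkeeping only — the
    counts are always drawn from the gain map.
    """
    geometry = geometry or DetectorGeometry()
    shape = geometry.shape
    if gain_map is None:
        gain_map = np.ones(shape)
    gain_map = np.asarray(gain_map, dtype=float)
    if gain_map.shape != shape:
        raise InputError(f"gain_map shape {gain_map.shape} != geometry {shape}")
    if defect_mask is None:
        defect_mask = np.zeros(shape, dtype=bool)
    defect_mask = np.asarray(defect_mask, dtype=bool)
    if defect_mask.shape != shape:
        raise InputError("defect_mask shape mismatch")
    if np.any(gain_map[~defect_mask] <= 0):
        raise InputError("gain must be strictly positive off-defect")
    if np.any(gain_map < 0):
        raise InputError("gain must be non-negative")
    if total_counts <= 0:
        raise InputError("total_counts must be positive")

    expected = total_counts * gain_map / gain_map.sum()
    counts = expected if noiseless else \
        rng_from_seed(seed).poisson(expected).astype(float)
    truth = GroundTruth({
        "gain_map": gain_map,
        "defect_mask": defect_mask,
        "n_defects": int(defect_mask.sum()),
        "total_counts": float(total_counts),
        "seed": seed,
        "noiseless": noiseless,
    })
    img = PlanarImage(counts, (geometry.pixel_pitch_mm, geometry.pixel_pitch_mm),
                      detector_id=detector_id, duration_s=duration_s)
    return img, truth


# ---------------------------------------------------------------------------
# Decay-source count-rate series
# ---------------------------------------------------------------------------

def decay_schedule(total_span_s: float, half_life_s: float = T_HALF_TC99M_S,
                   first_duration_s: float = 10.0,
                   interval_s: float = 1800.0,
                   max_duration_s: float = 600.0) -> list[tuple[float, float]]:
    """Default decay-source acquisition schedule.

    First acquisition ``first_duration_s`` long; subsequent durations are
    grown by ``2**(t/half_life)`` so the expected counts per point stay
    roughly constant as the source decays, capped at ``max_duration_s``.
    Acquisition start times are spaced ``interval_s`` apart.
    """
    if interval_s <= max_duration_s:
        raise InputError("interval must exceed the maximum duration")
    sched: list[tuple[float, float]] = []
    t = 0.0
    while t < total_span_s:
        dt = min(max_duration_s, first_duration_s * 2.0 ** (t / half_life_s))
        sched.append((t, dt))
        t += interval_s
    return sched


def gen_decay_series(initial_activity_MBq: float, half_life_s: float,
                     response: ResponseModel,
                     cps_per_MBq: float,
                     background_cps: float = 0.0,
                     schedule: Sequence[tuple[float, float]] | None = None,
                     seed: int | None = None, noiseless: bool = False,
                     isotope: str = "Tc99m",
                     quad_rtol: float = 1e-8,
                     ) -> tuple[CountRateSeries, GroundTruth]:
    """Timed count measurements of a decaying source seen through a
    count-rate response.

    The true input rate is ``ICR(t) = cps_per_MBq * A0 * 2**(-t/T_half)``;
    each recorded count integrates ``response(ICR(t)) + background`` over
    its acquisition window (closed form for the identity response,
    adaptive quadrature at relative tolerance ``quad_rtol`` otherwise).
    """
    if initial_activity_MBq < 0 or cps_per_MBq < 0 or background_cps < 0:
        raise InputError("activities and rates must be non-negative")
    if half_life_s <= 0:
        raise InputError("half-life must be positive")
    if schedule is None:
        schedule = decay_schedule(10 * half_life_s, half_life_s)
    starts = np.array([s for s, _ in schedule], dtype=float)
    durs = np.array([d for _, d in schedule], dtype=float)
    if np.any(durs <= 0):
        raise InputError("durations must be positive")
    ends = starts + durs
    if np.any(starts[1:] < ends[:-1]):
        raise InputError("schedule intervals must not overlap")

    tau = mean_lifetime(half_life_s)
    r0 = cps_per_MBq * initial_activity_MBq

    def icr(t: np.ndarray | float) -> np.ndarray | float:
        return r0 * np.exp(-np.asarray(t, dtype=float) / tau)

    expected = np.empty(len(schedule))
    identity = response.model_kind == "identity"
    for i, (t0, dt) in enumerate(zip(starts, durs)):
        if identity:
            src = tau * (icr(t0) - icr(t0 + dt))
        else:
            src, _ = integrate.quad(lambda t: response(icr(t)), t0, t0 + dt,
                                    epsrel=quad_rtol, epsabs=0.0, limit=200)
        expected[i] = src + background_cps * dt

    counts = expected if noiseless else \
        rng_from_seed(seed).poisson(expected).astype(float)
    pts = [CountRatePoint(float(t0), float(dt), float(k))
           for t0, dt, k in zip(starts, durs, counts)]
    series = CountRateSeries(pts, background_cps=background_cps,
                             half_life_s=half_life_s, isotope=isotope)
    truth = GroundTruth({
        "initial_rate_cps": r0,
        "half_life_s": half_life_s,
        "response_kind": response.model_kind,
        "response_parameters": dict(response.parameters),
        "background_cps": background_cps,
        "true_icr_cps": icr(starts),
        "true_ocr_cps": np.asarray(response(icr(starts))),
        "seed": seed,
        "noiseless": noiseless,
    })
    return series, truth


# ---------------------------------------------------------------------------
# Line and point sources
# ---------------------------------------------------------------------------

def _gauss_bin_integrals(edges: np.ndarray, center: float, fwhm: float
                         ) -> np.ndarray:
    """Integral of a unit-area Gaussian over each bin."""
    sigma = fwhm / FWHM_PER_SIGMA
    cdf = stats.norm.cdf(edges, loc=center, scale=sigma)
    return cdf[1:] - cdf[:-1]


def gen_line_image(geometry: DetectorGeometry | None = None,
                   line_axis: int = 1, fwhm_mm: float = 9.91,
                   total_counts: float = 10e6,
                   seed: int | None = None, noiseless: bool = False,
                   center_mm: float | None = None,
                   detector_id: str = "",
                   ) -> tuple[PlanarImage, GroundTruth]:
    """Static image of a line source: Gaussian LSF of the stated FWHM
    across the line, uniform along it.

    ``line_axis``: 0 = line runs transaxially, 1 = line runs axially
    (default — the profile is then taken across the 16 transaxial pixels
    ... for the default geometry a wide axial grid is more useful, so the
    default line runs along axis 1 with the spread over axis 0).
    """
    geometry = geometry or DetectorGeometry()
    pitch = geometry.pixel_pitch_mm
    shape = geometry.shape
    if line_axis not in (0, 1):
        raise InputError("line_axis must be 0 or 1")
    perp_axis = 1 - line_axis
    n_perp = shape[perp_axis]
    if total_counts <= 0:
        raise InputError("total_counts must be positive")
    sampling_ok = fwhm_mm > 2.0 * pitch
    if center_mm is None:
        center_mm = 0.5 * n_perp * pitch  # grid centre
    edges = pitch * np.arange(n_perp + 1)
    profile = _gauss_bin_integrals(edges, center_mm, fwhm_mm)
    profile = profile / profile.sum()
    expected_1d = total_counts * profile / shape[line_axis]
    if perp_axis == 0:
        expected = np.repeat(expected_1d[:, None], shape[1], axis=1)
    else:
        expected = np.repeat(expected_1d[None, :], shape[0], axis=0)
    counts = expected if noiseless else \
        rng_from_seed(seed).poisson(expected).astype(float)
    truth = GroundTruth({
        "fwhm_mm": fwhm_mm,
        "line_axis": line_axis,
        "center_mm": center_mm,
        "total_counts": float(total_counts),
        "sampling_adequate": bool(sampling_ok),
        "seed": seed,
        "noiseless": noiseless,
    })
    if not sampling_ok:
        truth.params["warning"] = (
            f"FWHM {fwhm_mm} mm below the 2-pixel sampling limit "
            f"({2 * pitch:.2f} mm); width estimates will be biased")
    img = PlanarImage(counts, (pitch, pitch), detector_id=detector_id)
    return img, truth


def gen_point_volume(source_positions_mm: Sequence[Sequence[float]],
                     fwhm_mm: Sequence[float] | float,
                     voxel_mm: float = 2.46,
                     counts_per_source: float = 1e6,
                     grid_shape: tuple[int, int, int] = (96, 96, 96),
                     seed: int | None = None, noiseless: bool = False,
                     ) -> tuple[VolumeImage, GroundTruth]:
    """Reconstructed-space volume of 3-D Gaussian point-spread blobs.

    Positions are in mm relative to the volume centre (X, Y transverse,
    Z axial); ``fwhm_mm`` is scalar (isotropic) or per-axis.
    """
    positions = np.atleast_2d(np.asarray(source_positions_mm, dtype=float))
    if positions.shape[1] != 3:
        raise InputError("positions must be 3-vectors")
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm <= 0):
        raise InputError("FWHM must be positive")
    if counts_per_source <= 0:
        raise InputError("counts_per_source must be positive")
    half_extent = np.array([0.5 * n * voxel_mm for n in grid_shape])
    if np.any(np.abs(positions) > half_extent - 2 * fwhm.max()):
        raise InputError("source positions must lie inside the volume")
    if positions.shape[0] > 1:
        from scipy.spatial.distance import pdist
        if pdist(positions).min() <= 5.0 * fwhm.max():
            raise InputError("sources must be separated by > 5x max FWHM "
                             "(overlapping blobs)")

    axes_edges = [voxel_mm * np.arange(n + 1) - half_extent[a]
                  for a, n in enumerate(grid_shape)]
    expected = np.zeros(grid_shape)
    for pos in positions:
        gx = _gauss_bin_integrals(axes_edges[0], pos[0], fwhm[0])
        gy = _gauss_bin_integrals(axes_edges[1], pos[1], fwhm[1])
        gz = _gauss_bin_integrals(axes_edges[2], pos[2], fwhm[2])
        blob = np.einsum("i,j,k->ijk", gx, gy, gz)
        expected += counts_per_source * blob / blob.sum()
    counts = expected if noiseless else \
        rng_from_seed(seed).poisson(expected).astype(float)
    truth = GroundTruth({
        "source_positions_mm": positions,
        "fwhm_mm": fwhm,
        "voxel_mm": voxel_mm,
        "counts_per_source": float(counts_per_source),
        "seed": seed,
        "noiseless": noiseless,
    })
    vol = VolumeImage(counts, (voxel_mm, voxel_mm, voxel_mm))
    return vol, truth


def gen_line_volume(line_positions_mm: Sequence[Sequence[float]],
                    fwhm_mm: Sequence[float] | float,
                    voxel_mm: float = 2.46,
                    counts_per_line: float = 1e6,
                    grid_shape: tuple[int, int, int] = (96, 96, 48),
                    seed: int | None = None, noiseless: bool = False,
                    ) -> tuple[VolumeImage, GroundTruth]:
    """Reconstructed-space volume of axial line sources (triple-line
    phantom layout): each line runs along Z at a transverse (x, y)
    position with a Gaussian transverse spread of the stated per-axis
    FWHM, uniform along its extent.
    """
    positions = np.atleast_2d(np.asarray(line_positions_mm, dtype=float))
    if positions.shape[1] != 2:
        raise InputError("line positions must be transverse (x, y) pairs")
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (2,)).copy()
    if np.any(fwhm <= 0):
        raise InputError("FWHM must be positive")
    nx, ny, nz = grid_shape
    x_edges = voxel_mm * np.arange(nx + 1) - 0.5 * nx * voxel_mm
    y_edges = voxel_mm * np.arange(ny + 1) - 0.5 * ny * voxel_mm
    expected = np.zeros(grid_shape)
    for px, py in positions:
        gx = _gauss_bin_integrals(x_edges, px, fwhm[0])
        gy = _gauss_bin_integrals(y_edges, py, fwhm[1])
        plane = np.outer(gx, gy)
        expected += counts_per_line * plane[:, :, None] / (plane.sum() * nz)
    counts = expected if noiseless else \
        rng_from_seed(seed).poisson(expected).astype(float)
    truth = GroundTruth({
        "line_positions_mm": positions,
        "fwhm_mm": fwhm,
        "voxel_mm": voxel_mm,
        "counts_per_line": float(counts_per_line),
        "seed": seed,
        "noiseless": noiseless,
    })
    return VolumeImage(counts, (voxel_mm, voxel_mm, voxel_mm)), truth


# ---------------------------------------------------------------------------
# IEC body phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IECPhantomSpec:
    """Geometry of the (cylindrically approximated) IEC body phantom.

    Six fillable spheres on a coplanar ring in the central transverse
    plane; a low-density lung-insert cylinder along the axis. The study's
    sphere set is 13, 17, 22, 28, 28 and 37 mm inner diameter with the
    four smallest hot and the two largest cold.
    """

    sphere_diameters_mm: tuple[float, ...] = (13.0, 17.0, 22.0, 28.0, 28.0, 37.0)
    hot_flags: tuple[bool, ...] = (True, True, True, True, False, False)
    ring_radius_mm: float = 57.2
    wall_radius_mm: float = 147.0
    lung_diameter_mm: float = 50.0

    def sphere_centers_mm(self) -> np.ndarray:
        n = len(self.sphere_diameters_mm)
        ang = 2.0 * math.pi * np.arange(n) / n
        return np.column_stack([self.ring_radius_mm * np.cos(ang),
                                self.ring_radius_mm * np.sin(ang),
                                np.zeros(n)])


def gen_iec_volume(phantom: IECPhantomSpec | None = None,
                   sphere_to_background_ratio: float = 8.0,
                   background_level: float = 100.0,
                   lung_insert: bool = True,
                   psf_fwhm_mm: float = 0.0,
                   voxel_mm: float = 2.46,
                   grid_shape: tuple[int, int, int] = (128, 128, 49),
                   seed: int | None = None, noiseless: bool = False,
                   ) -> tuple[VolumeImage, GroundTruth]:
    """Voxelized IEC body phantom in reconstructed space.

    Hot spheres are filled at ``sphere_to_background_ratio`` times the
    background counts/voxel, cold spheres and the lung insert at zero,
    optionally convolved with a Gaussian PSF and Poisson sampled. Partial
    volume at boundaries is modelled by the voxel-centre membership rule
    (no sub-voxel antialiasing) — consistent with the ROI rule used by the
    contrast analysis. The default grid has an odd axial dimension so one
    slice lies exactly on the sphere plane (the full-recovery limit is
    then exact rather than diluted by a half-voxel slice offset).
    """
    phantom = phantom or IECPhantomSpec()
    dia = np.asarray(phantom.sphere_diameters_mm, dtype=float)
    hot = np.asarray(phantom.hot_flags, dtype=bool)
    if dia.size != hot.size:
        raise InputError("one hot flag per sphere required")
    if np.any(dia <= 0):
        raise InputError("sphere diameters must be positive")
    if sphere_to_background_ratio <= 0 or background_level < 0:
        raise InputError("levels must be positive")
    centers = phantom.sphere_centers_mm()
    # overlap / containment checks
    for i in range(len(dia)):
        ri = 0.5 * dia[i]
        if np.hypot(centers[i, 0], centers[i, 1]) + ri >= phantom.wall_radius_mm:
            raise InputError("sphere outside phantom wall")
        for j in range(i + 1, len(dia)):
            if np.linalg.norm(centers[i] - centers[j]) <= ri + 0.5 * dia[j]:
                raise InputError("spheres overlap")

    nx, ny, nz = grid_shape
    x = (np.arange(nx) + 0.5) * voxel_mm - 0.5 * nx * voxel_mm
    y = (np.arange(ny) + 0.5) * voxel_mm - 0.5 * ny * voxel_mm
    z = (np.arange(nz) + 0.5) * voxel_mm - 0.5 * nz * voxel_mm
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    R2 = X ** 2 + Y ** 2

    expected = np.zeros(grid_shape)
    body = R2 < phantom.wall_radius_mm ** 2
    expected[body] = background_level
    if lung_insert:
        lung = R2 < (0.5 * phantom.lung_diameter_mm) ** 2
        expected[lung] = 0.0
    for c, d, is_hot in zip(centers, dia, hot):
        mask = ((X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2
                < (0.5 * d) ** 2)
        expected[mask] = (background_level * sphere_to_background_ratio
                          if is_hot else 0.0)

    if psf_fwhm_mm > 0:
        from scipy.ndimage import gaussian_filter
        sigma_vox = psf_fwhm_mm / FWHM_PER_SIGMA / voxel_mm
        expected = gaussian_filter(expected, sigma_vox, mode="constant")

    counts = expected if noiseless else \
        rng_from_seed(seed).poisson(expected).astype(float)
    truth = GroundTruth({
        "sphere_diameters_mm": dia,
        "hot_flags": hot,
        "sphere_centers_mm": centers,
        "ring_radius_mm": phantom.ring_radius_mm,
        "wall_radius_mm": phantom.wall_radius_mm,
        "lung_diameter_mm": phantom.lung_diameter_mm,
        "lung_insert": lung_insert,
        "sphere_to_background_ratio": sphere_to_background_ratio,
        "background_level": background_level,
        "psf_fwhm_mm": psf_fwhm_mm,
        "voxel_mm": voxel_mm,
        "seed": seed,
        "noiseless": noiseless,
    })
    vol = VolumeImage(counts, (voxel_mm, voxel_mm, voxel_mm),
                      annotations={"phantom": "IEC"})
    return vol, truth


# ---------------------------------------------------------------------------
# Uniform cylinder (volume sensitivity / detector-detector variation)
# ---------------------------------------------------------------------------

def gen_cylinder_projections(n_detectors: int = 12,
                             sensitivity_factors: Sequence[float] | None = None,
                             activity_conc_MBq_per_cc: float = 0.118,
                             cylinder_diameter_mm: float = 200.0,
                             cylinder_length_mm: float = 200.0,
                             duration_s: float = 900.0,
                             cps_per_detector_at_unit_factor: float = 1e3,
                             image_shape: tuple[int, int] = (16, 112),
                             seed: int | None = None, noiseless: bool = False,
                             ) -> tuple[list[PlanarImage], GroundTruth]:
    """Per-detector summed count images of a uniform cylinder acquisition.

    Detector ``d`` records an expected total of
    ``sensitivity_factors[d] * cps_per_detector_at_unit_factor * duration``
    counts, spread uniformly over its image; the activity concentration and
    cylinder geometry are carried through to the ground truth for the
    volume-sensitivity bookkeeping.
    """
    if sensitivity_factors is None:
        sensitivity_factors = [1.0] * n_detectors
    factors = np.asarray(sensitivity_factors, dtype=float)
    if factors.size != n_detectors:
        raise InputError("one sensitivity factor per detector required")
    if np.any((factors <= 0) | (factors > 1.0)):
        raise InputError("sensitivity factors must lie in (0, 1]")
    if duration_s <= 0:
        raise InputError("duration must be positive")
    if activity_conc_MBq_per_cc <= 0:
        raise InputError("activity concentration must be positive")

    rng = rng_from_seed(seed)
    n_pix = image_shape[0] * image_shape[1]
    images: list[PlanarImage] = []
    totals = np.empty(n_detectors)
    for d in range(n_detectors):
        total = factors[d] * cps_per_detector_at_unit_factor * duration_s
        expected = np.full(image_shape, total / n_pix)
        counts = expected if noiseless else rng.poisson(expected).astype(float)
        totals[d] = counts.sum()
        images.append(PlanarImage(counts, detector_id=f"D{d + 1:02d}",
                                  duration_s=duration_s))
    truth = GroundTruth({
        "sensitivity_factors": factors,
        "expected_totals": factors * cps_per_detector_at_unit_factor * duration_s,
        "activity_conc_MBq_per_cc": activity_conc_MBq_per_cc,
        "cylinder_diameter_mm": cylinder_diameter_mm,
        "cylinder_length_mm": cylinder_length_mm,
        "duration_s": duration_s,
        "true_dds_percent": 100.0 * (factors.max() - factors.min()) / factors.max(),
        "seed": seed,
        "noiseless": noiseless,
    })
    return images, truth


# ---------------------------------------------------------------------------
# Planar-sensitivity acquisitions
# ---------------------------------------------------------------------------

def gen_sensitivity_counts(true_sensitivity_cps_per_MBq: float,
                           A_cal_MBq: float,
                           delay_s: float,
                           duration_s: float,
                           half_life_s: float = T_HALF_TC99M_S,
                           seed: int | None = None, noiseless: bool = False,
                           ) -> tuple[float, GroundTruth]:
    """Total counts recorded by one detector viewing a calibrated decaying
    source, for planar-sensitivity parameter recovery.

    The expected total integrates ``S * A_cal * exp(-t/tau)`` from the
    acquisition start (``delay_s`` after calibration) over ``duration_s``.
    """
    if true_sensitivity_cps_per_MBq <= 0 or A_cal_MBq <= 0:
        raise InputError("sensitivity and activity must be positive")
    if duration_s <= 0 or delay_s < 0:
        raise InputError("bad timing")
    tau = mean_lifetime(half_life_s)
    expected = (true_sensitivity_cps_per_MBq * A_cal_MBq * tau
                * math.exp(-delay_s / tau) * (-math.expm1(-duration_s / tau)))
    counts = expected if noiseless else \
        float(rng_from_seed(seed).poisson(expected))
    truth = GroundTruth({
        "true_sensitivity_cps_per_MBq": true_sensitivity_cps_per_MBq,
        "A_cal_MBq": A_cal_MBq,
        "delay_s": delay_s,
        "duration_s": duration_s,
        "half_life_s": half_life_s,
        "expected_counts": expected,
        "seed": seed,
        "noiseless": noiseless,
    })
    return counts, truth
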