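"""Planar and SPECT spatial resolution.

Planar: the line-spread function of a static line-source image is
extracted per detector (tail-background subtraction, summation along the
line), its FWHM and FWTM estimated with the shared parabolic-vertex /
linear-interpolation estimator, and the resolution measured at the
150 mm collimator radius is extrapolated to 100 mm with the
effective-septal-length formula

    R_target = (target + l_eff) / (measured + l_eff) * R_measured

(l_eff = 17.72 mm for Tc-99m).

SPECT: point-source volumes are reduced to three orthogonal summed views
per source (transverse, coronal, sagittal) over a slab centred on each
source; widths are measured on profiles through the peak and aggregated
into the standard report entries — central transaxial / central axial
and peripheral radial / tangential / axial for the three-point in-air
layout, or central / radial / tangential for the triple-line-in-scatter
layout. Views are analyzed at native voxel pitch (no upsampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .datatypes import (
    AnalysisError,
    FWHM_PER_SIGMA,
    InputError,
    PlanarImage,
    VolumeImage,
)
from .spectrometry import PeakFit, interpolated_width, parabolic_peak

__all__ = [
    "Profile",
    "profile_width",
    "lsf_from_planar",
    "extrapolate_resolution",
    "planar_resolution_report",
    "SourceViews",
    "spect_point_views",
    "spect_resolution_report",
    "ResolutionResult",
]

TILT_LIMIT_DEG = 5.0
SLAB_FWHM_FACTOR = 4.0       # slab half-width = 4 x coarse FWHM estimate
LINE_TRIM_FRACTION = 0.8     # central fraction of a line used for averaging


@dataclass
class Profile:
    """1-D spatial profile on a uniform millimetre grid."""

    positions_mm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions_mm = np.asarray(self.positions_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_mm.size != self.values.size:
            raise InputError("positions and values must match")
        d = np.diff(self.positions_mm)
        if d.size and not np.allclose(d, d[0], rtol=1e-9):
            raise InputError("profile spacing must be uniform")

    @property
    def spacing_mm(self) -> float:
        return float(self.positions_mm[1] - self.positions_mm[0])


def profile_width(profile: Profile, fraction: float = 0.5) -> float:
    """Width of the profile at ``fraction`` of the parabolic peak height,
    in mm (0.5 -> FWHM, 0.1 -> FWTM)."""
    peak = parabolic_peak(profile.positions_mm, profile.values,
                          min_significance=0.0)
    return interpolated_width(profile.positions_mm, profile.values,
                              peak, fraction)


def lsf_from_planar(image: PlanarImage, line_axis: int = 1,
                    band_mm: float | None = None) -> Profile:
    """Line-spread function perpendicular to an axis-aligned line source.

    The line tilt is estimated by regressing the per-row centroid against
    position along the line; images tilted more than 5 degrees are
    rejected. The background pedestal (mean of the outer 20 % tails of
    the summed profile) is subtracted before returning.
    """
    if line_axis not in (0, 1):
        raise InputError("line_axis must be 0 or 1")
    perp = 1 - line_axis
    counts = image.counts if line_axis == 1 else image.counts.T
    # counts is now [perpendicular, along]
    pitch_perp = image.pixel_pitch_mm[perp]
    pitch_along = image.pixel_pitch_mm[line_axis]

    col_tot = counts.sum(axis=0)
    use = col_tot > 0
    if use.sum() >= 2:
        pos_perp = (np.arange(counts.shape[0]) + 0.5) * pitch_perp
        centroids = (counts[:, use] * pos_perp[:, None]).sum(axis=0) / col_tot[use]
        along = (np.nonzero(use)[0] + 0.5) * pitch_along
        slope = np.polyfit(along, centroids, 1)[0]
        tilt_deg = math.degrees(math.atan(slope))
        if abs(tilt_deg) > TILT_LIMIT_DEG:
            raise InputError(
                f"line tilt {tilt_deg:.2f} deg exceeds {TILT_LIMIT_DEG} deg")

    if band_mm is not None:
        n_along = counts.shape[1]
        center = 0.5 * n_along * pitch_along
        lo = max(0, int((center - 0.5 * band_mm) / pitch_along))
        hi = min(n_along, int(np.ceil((center + 0.5 * band_mm) / pitch_along)))
        counts = counts[:, lo:hi]

    profile = counts.sum(axis=1)
    n = profile.size
    n_tail = max(1, int(0.1 * n))          # 10 % on each side = outer 20 %
    pedestal = float(np.concatenate([profile[:n_tail], profile[-n_tail:]]).mean())
    values = np.clip(profile - pedestal, 0.0, None)
    positions = (np.arange(n) + 0.5) * pitch_perp
    return Profile(positions, values)


def extrapolate_resolution(R_measured_mm: float, measured_distance_mm: float,
                           target_distance_mm: float, l_eff_mm: float
                           ) -> float:
    """Collimator-distance extrapolation of a measured resolution."""
    if measured_distance_mm <= 0 or target_distance_mm <= 0:
        raise InputError("distances must be positive")
    if l_eff_mm < 0:
        raise InputError("effective septal length must be non-negative")
    return ((target_distance_mm + l_eff_mm)
            / (measured_distance_mm + l_eff_mm) * R_measured_mm)


@dataclass
class ResolutionResult:
    """Planar system resolution at the measured and extrapolated distances."""

    measured_distance_mm: float
    target_distance_mm: float
    l_eff_mm: float
    per_detector: list[dict] = field(default_factory=list)

    def _stat(self, key: str) -> dict:
        vals = np.array([d[key] for d in self.per_detector])
        return {"average": float(vals.mean()),
                "range": [float(vals.min()), float(vals.max())]}

    def to_dict(self) -> dict:
        out = {
            "measured_distance_mm": self.measured_distance_mm,
            "target_distance_mm": self.target_distance_mm,
            "l_eff_mm": self.l_eff_mm,
            "per_detector": self.per_detector,
        }
        for key in ("fwhm_measured_mm", "fwtm_measured_mm",
                    "fwhm_target_mm", "fwtm_target_mm"):
            out[key] = self._stat(key)
        return out


def planar_resolution_report(images: Sequence[PlanarImage],
                             line_axis: int = 1,
                             l_eff_mm: float = 17.72,
                             measured_distance_mm: float = 150.0,
                             target_distance_mm: float = 100.0,
                             band_mm: float | None = None
                             ) -> ResolutionResult:
    """FWHM/FWTM of the LSF per detector, with the 100 mm extrapolation."""
    if not images:
        raise InputError("need at least one image")
    result = ResolutionResult(measured_distance_mm, target_distance_mm, l_eff_mm)
    for img in images:
        prof = lsf_from_planar(img, line_axis, band_mm)
        fwhm = profile_width(prof, 0.5)
        fwtm = profile_width(prof, 0.1)
        result.per_detector.append({
            "detector_id": img.detector_id,
            "fwhm_measured_mm": fwhm,
            "fwtm_measured_mm": fwtm,
            "fwhm_target_mm": extrapolate_resolution(
                fwhm, measured_distance_mm, target_distance_mm, l_eff_mm),
            "fwtm_target_mm": extrapolate_resolution(
                fwtm, measured_distance_mm, target_distance_mm, l_eff_mm),
        })
    return result


# ---------------------------------------------------------------------------
# SPECT point-source views
# ---------------------------------------------------------------------------

@dataclass
class SourceViews:
    """Orthogonal summed views of one point (or line) source."""

    center_mm: np.ndarray                 # refined centroid, volume frame
    transverse: np.ndarray                # (X, Y), summed over Z
    coronal: np.ndarray                   # (X, Z), summed over Y
    sagittal: np.ndarray                  # (Y, Z), summed over X
    voxel_mm: tuple[float, float, float]
    origin_idx: tuple[int, int, int]      # slab lower corner in the volume
    is_central: bool = False


def _coarse_blob(volume: VolumeImage, pos_mm: np.ndarray,
                 half_width_mm: float = 25.0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Centroid (mm) and per-axis coarse FWHM of the counts near a
    position, from first/second moments."""
    sl = []
    for a in range(3):
        coords = volume.axis_coords(a)
        inside = np.nonzero(np.abs(coords - pos_mm[a]) <= half_width_mm)[0]
        if inside.size == 0:
            raise InputError("expected position outside the volume")
        sl.append(slice(int(inside[0]), int(inside[-1]) + 1))
    sub = volume.counts[tuple(sl)]
    tot = sub.sum()
    if tot <= 0:
        raise AnalysisError("no counts near the expected source position")
    centroid = np.empty(3)
    fwhm = np.empty(3)
    for a in range(3):
        coords = volume.axis_coords(a)[sl[a]]
        marg = sub.sum(axis=tuple(i for i in range(3) if i != a))
        centroid[a] = (marg * coords).sum() / tot
        var = (marg * (coords - centroid[a]) ** 2).sum() / tot
        fwhm[a] = FWHM_PER_SIGMA * math.sqrt(max(var, 1e-12))
    return centroid, fwhm


def spect_point_views(volume: VolumeImage,
                      expected_positions_mm: Sequence[Sequence[float]],
                      slab_factor: float = SLAB_FWHM_FACTOR
                      ) -> list[SourceViews]:
    """Per-source orthogonal summed views.

    For each expected source position a bounding slab of half-width
    ``slab_factor`` times the coarse FWHM estimate is centred on the
    refined centroid and summed along each axis. Overlapping slabs are
    rejected.
    """
    positions = np.atleast_2d(np.asarray(expected_positions_mm, dtype=float))
    views: list[SourceViews] = []
    boxes: list[tuple[tuple[int, int], ...]] = []
    radii = np.hypot(positions[:, 0], positions[:, 1])
    central_idx = int(np.argmin(radii))
    for s, pos in enumerate(positions):
        centroid, coarse = _coarse_blob(volume, pos)
        slices = []
        box = []
        for a in range(3):
            coords = volume.axis_coords(a)
            half = slab_factor * coarse[a]
            inside = np.nonzero(np.abs(coords - centroid[a]) <= half)[0]
            lo, hi = int(inside[0]), int(inside[-1]) + 1
            slices.append(slice(lo, hi))
            box.append((lo, hi))
        for other in boxes:
            if all(b[0] < o[1] and o[0] < b[1] for b, o in zip(box, other)):
                raise InputError("source slabs overlap; increase separation "
                                 "or reduce slab_factor")
        boxes.append(tuple(box))
        sub = volume.counts[tuple(slices)]
        views.append(SourceViews(
            center_mm=centroid,
            transverse=sub.sum(axis=2),
            coronal=sub.sum(axis=1),
            sagittal=sub.sum(axis=0),
            voxel_mm=volume.voxel_mm,
            origin_idx=(slices[0].start, slices[1].start, slices[2].start),
            is_central=(s == central_idx),
        ))
    return views


def _view_profile(view: np.ndarray, spacing: tuple[float, float],
                  center_idx: tuple[float, float], angle_rad: float
                  ) -> Profile:
    """Profile through a 2-D view's peak along a direction in the view
    plane, sampled at the finer native pitch (bilinear off-grid)."""
    step = min(spacing)
    n_half = int(math.ceil(max(view.shape[0] * spacing[0],
                               view.shape[1] * spacing[1]) / step))
    s = step * np.arange(-n_half, n_half + 1)
    u = np.array([math.cos(angle_rad), math.sin(angle_rad)])
    rows = center_idx[0] + s * u[0] / spacing[0]
    cols = center_idx[1] + s * u[1] / spacing[1]
    vals = map_coordinates(view, np.vstack([rows, cols]), order=1,
                           mode="constant", cval=0.0)
    return Profile(s, vals)


def _axis_widths(sv: SourceViews, volume: VolumeImage,
                 fraction: float = 0.5) -> dict[str, float]:
    """FWHM along each grid axis from the orthogonal views' marginals."""
    out: dict[str, float] = {}
    pairs = {"transverse": (0, 1), "coronal": (0, 2), "sagittal": (1, 2)}
    for name, (a0, a1) in pairs.items():
        view = getattr(sv, name)
        origin = {"transverse": (sv.origin_idx[0], sv.origin_idx[1]),
                  "coronal": (sv.origin_idx[0], sv.origin_idx[2]),
                  "sagittal": (sv.origin_idx[1], sv.origin_idx[2])}[name]
        for local_axis, vol_axis in ((0, a0), (1, a1)):
            marg = view.sum(axis=1 - local_axis)
            coords = volume.axis_coords(vol_axis)[
                origin[local_axis]:origin[local_axis] + marg.size]
            key = f"{'xyz'[vol_axis]}_{name}"
            out[key] = profile_width(Profile(coords, marg), fraction)
    return out


def _radial_tangential(sv: SourceViews, volume: VolumeImage,
                       fraction: float = 0.5) -> tuple[float, float]:
    """FWHM along / perpendicular to the transverse radius vector."""
    x0, y0 = sv.center_mm[0], sv.center_mm[1]
    theta = math.atan2(y0, x0)
    # snap to a grid axis when the layout is axis-aligned
    snapped = round(theta / (0.5 * math.pi)) * 0.5 * math.pi
    if abs(theta - snapped) < 1e-6:
        theta = snapped
    widths = _axis_widths(sv, volume, fraction)
    if abs(math.sin(theta)) < 1e-9:          # radius along X
        return widths["x_transverse"], widths["y_transverse"]
    if abs(math.cos(theta)) < 1e-9:          # radius along Y
        return widths["y_transverse"], widths["x_transverse"]
    spacing = (sv.voxel_mm[0], sv.voxel_mm[1])
    cx = sv.center_mm[0] / sv.voxel_mm[0] + 0.5 * volume.counts.shape[0] \
        - 0.5 - sv.origin_idx[0]
    cy = sv.center_mm[1] / sv.voxel_mm[1] + 0.5 * volume.counts.shape[1] \
        - 0.5 - sv.origin_idx[1]
    prof_r = _view_profile(sv.transverse, spacing, (cx, cy), theta)
    prof_t = _view_profile(sv.transverse, spacing, (cx, cy),
                           theta + 0.5 * math.pi)
    return profile_width(prof_r, fraction), profile_width(prof_t, fraction)


def spect_resolution_report(views: Sequence[SourceViews] | None,
                            volume: VolumeImage,
                            layout: str = "three_point_air",
                            line_positions_mm: Sequence[Sequence[float]] | None = None,
                            fraction: float = 0.5) -> dict:
    """Aggregate per-source widths into the standard report entries.

    ``three_point_air``: central transaxial (mean of the central source's
    X/Y widths), central axial (mean of its Z widths from the coronal and
    sagittal views), and peripheral radial / tangential / axial averaged
    over the off-axis sources, each with its range. A missing peripheral
    pair yields absent entries plus a flag.

    ``triple_line_scatter``: central / radial / tangential widths of
    three axial lines, per-slice profiles averaged over the central 80 %
    of the line extent (``line_positions_mm`` gives the transverse (x, y)
    line positions).
    """
    if layout == "three_point_air":
        if not views:
            raise InputError("views required for the three-point layout")
        report: dict = {"layout": layout, "flags": []}
        central = [v for v in views if v.is_central]
        peripheral = [v for v in views if not v.is_central]
        if central:
            sv = central[0]
            w = _axis_widths(sv, volume, fraction)
            report["central_transaxial_mm"] = _mr(
                [0.5 * (w["x_transverse"] + w["y_transverse"])])
            report["central_axial_mm"] = _mr(
                [0.5 * (w["z_coronal"] + w["z_sagittal"])])
        if peripheral:
            rad, tan, axial = [], [], []
            for sv in peripheral:
                r, t = _radial_tangential(sv, volume, fraction)
                w = _axis_widths(sv, volume, fraction)
                rad.append(r)
                tan.append(t)
                axial.append(0.5 * (w["z_coronal"] + w["z_sagittal"]))
            report["peripheral_radial_mm"] = _mr(rad)
            report["peripheral_tangential_mm"] = _mr(tan)
            report["peripheral_axial_mm"] = _mr(axial)
        else:
            report["flags"].append("no_peripheral_sources")
        return report

    if layout == "triple_line_scatter":
        if line_positions_mm is None:
            raise InputError("line_positions_mm required for the triple-line "
                             "layout")
        return _triple_line_report(volume, line_positions_mm, fraction)

    raise InputError(f"unknown layout {layout!r}")


def _mr(values: Sequence[float]) -> dict:
    arr = np.asarray(values, dtype=float)
    return {"average": float(arr.mean()),
            "range": [float(arr.min()), float(arr.max())]}


def _triple_line_report(volume: VolumeImage,
                        line_positions_mm: Sequence[Sequence[float]],
                        fraction: float) -> dict:
    positions = np.atleast_2d(np.asarray(line_positions_mm, dtype=float))
    nz = volume.counts.shape[2]
    trim = int(round(0.5 * (1.0 - LINE_TRIM_FRACTION) * nz))
    slices = range(trim, nz - trim)
    radii = np.hypot(positions[:, 0], positions[:, 1])
    central_idx = int(np.argmin(radii))

    xcoords = volume.axis_coords(0)
    ycoords = volume.axis_coords(1)
    report: dict = {"layout": "triple_line_scatter", "flags": []}
    central_vals, radial_vals, tangential_vals = [], [], []
    for i, (px, py) in enumerate(positions[:, :2]):
        per_slice_a, per_slice_b = [], []
        for k in slices:
            sl = volume.counts[:, :, k]
            ix = int(np.argmin(np.abs(xcoords - px)))
            iy = int(np.argmin(np.abs(ycoords - py)))
            prof_x = Profile(xcoords, sl[:, iy])
            prof_y = Profile(ycoords, sl[ix, :])
            theta = math.atan2(py, px)
            if i == central_idx or abs(math.sin(theta)) < 1e-9:
                a, b = profile_width(prof_x, fraction), \
                    profile_width(prof_y, fraction)
            elif abs(math.cos(theta)) < 1e-9:
                a, b = profile_width(prof_y, fraction), \
                    profile_width(prof_x, fraction)
            else:
                spacing = (volume.voxel_mm[0], volume.voxel_mm[1])
                cx = px / volume.voxel_mm[0] + 0.5 * sl.shape[0] - 0.5
                cy = py / volume.voxel_mm[1] + 0.5 * sl.shape[1] - 0.5
                a = profile_width(
                    _view_profile(sl, spacing, (cx, cy), theta), fraction)
                b = profile_width(
                    _view_profile(sl, spacing, (cx, cy),
                                  theta + 0.5 * math.pi), fraction)
            per_slice_a.append(a)
            per_slice_b.append(b)
        if i == central_idx:
            central_vals.append(0.5 * (np.mean(per_slice_a)
                                       + np.mean(per_slice_b)))
        else:
            radial_vals.append(float(np.mean(per_slice_a)))
            tangential_vals.append(float(np.mean(per_slice_b)))
    if central_vals:
        report["central_mm"] = _mr(central_vals)
    if radial_vals:
        report["radial_mm"] = _mr(radial_vals)
        report["tangential_mm"] = _mr(tangential_vals)
    else:
        report["flags"].append("no_peripheral_lines")
    return report
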