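"""IEC body-phantom tomographic contrast analysis.

Circular ROIs with diameters equal to the sphere inner diameters are
placed on the transverse slice through the sphere centres; background
ROIs of each size are placed at twelve template positions on a ring
between the sphere ring and the phantom wall, on the central slice and
the slices closest to +/-1 and +/-2 cm (K = 60 per size). From the ROI
means the analysis reports:

    hot contrast recovery    Q_H = (c_H/c_B - 1) / (a_H/a_B - 1) * 100 %
    cold contrast recovery   Q_C = (1 - c_C/c_B) * 100 %
    background variability   N_j = SD_j / c_B_j * 100 %   (K-1 denominator)
    residual lung error      dC_lung_i = C_lung_i / C_B_37mm * 100 %

with a 30 mm ROI on the lung insert per slice. ROI membership is
voxel-centre strictly inside the circle, on a single slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import AnalysisError, InputError, VolumeImage

__all__ = [
    "SphereSpec",
    "RoiSet",
    "place_rois",
    "roi_mean",
    "contrast_recovery",
    "background_variability",
    "lung_error",
    "analyze_contrast",
]

BACKGROUND_MARGIN_MM = 15.0
N_BACKGROUND_POSITIONS = 12
SLICE_OFFSETS_MM = (0.0, 10.0, -10.0, 20.0, -20.0)
LUNG_ROI_DIAMETER_MM = 30.0


@dataclass(frozen=True)
class SphereSpec:
    center_mm: tuple[float, float, float]
    diameter_mm: float
    hot: bool


@dataclass
class CircleRoi:
    """One circular ROI on one transverse slice."""

    center_mm: tuple[float, float]
    diameter_mm: float
    slice_index: int


@dataclass
class RoiSet:
    sphere_rois: list[tuple[SphereSpec, CircleRoi]]
    background_rois: dict[float, list[CircleRoi]]   # by diameter
    lung_rois: list[CircleRoi] = field(default_factory=list)
    slice_offsets_mm: list[float] = field(default_factory=list)


def _nearest_slice(volume: VolumeImage, z_mm: float) -> int:
    z = volume.axis_coords(2)
    return int(np.argmin(np.abs(z - z_mm)))


def _roi_mask(volume: VolumeImage, roi: CircleRoi) -> np.ndarray:
    """Boolean transverse mask: voxel centre strictly inside the circle."""
    x = volume.axis_coords(0)
    y = volume.axis_coords(1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    r2 = (X - roi.center_mm[0]) ** 2 + (Y - roi.center_mm[1]) ** 2
    return r2 < (0.5 * roi.diameter_mm) ** 2


def roi_mean(volume: VolumeImage, roi: CircleRoi) -> float:
    mask = _roi_mask(volume, roi)
    if not mask.any():
        raise AnalysisError("ROI contains no voxel centres")
    return float(volume.counts[:, :, roi.slice_index][mask].mean())


def place_rois(volume: VolumeImage,
               spheres: Sequence[SphereSpec],
               lung_center_mm: tuple[float, float] = (0.0, 0.0),
               wall_radius_mm: float = 147.0,
               background_ring_radius_mm: float = 108.0,
               ) -> RoiSet:
    """Automatic ROI placement.

    Sphere ROIs sit on the slice nearest each sphere centre. Background
    ROI centres start from twelve 30-degree template positions offset 15
    degrees from the sphere ring; positions violating the 15 mm margins
    to any sphere or to the phantom wall are nudged radially inward/
    outward before placement fails. Slice offsets snap to the nearest
    available slice ("as close as possible" to 0, +/-10, +/-20 mm).
    """
    if not spheres:
        raise InputError("need at least one sphere")
    slice_indices = [_nearest_slice(volume, off) for off in SLICE_OFFSETS_MM]
    z = volume.axis_coords(2)
    actual_offsets = [float(z[i]) for i in slice_indices]

    sphere_rois = []
    for sp in spheres:
        k = _nearest_slice(volume, sp.center_mm[2])
        sphere_rois.append((sp, CircleRoi((sp.center_mm[0], sp.center_mm[1]),
                                          sp.diameter_mm, k)))

    def margin_violation(cx: float, cy: float, radius: float) -> float:
        """Worst margin deficit (positive = violated) for a centre."""
        worst = (np.hypot(cx, cy) + radius + BACKGROUND_MARGIN_MM
                 - wall_radius_mm)
        for sp in spheres:
            d = np.hypot(cx - sp.center_mm[0], cy - sp.center_mm[1])
            need = radius + 0.5 * sp.diameter_mm + BACKGROUND_MARGIN_MM
            worst = max(worst, need - d)
        return worst

    background: dict[float, list[CircleRoi]] = {}
    diameters = sorted({sp.diameter_mm for sp in spheres})
    angles = np.deg2rad(15.0 + 30.0 * np.arange(N_BACKGROUND_POSITIONS))
    for dia in diameters:
        radius = 0.5 * dia
        centers = []
        for ang in angles:
            placed = False
            for ring in np.arange(background_ring_radius_mm,
                                  background_ring_radius_mm + 25.0, 2.5):
                cx, cy = ring * math.cos(ang), ring * math.sin(ang)
                if margin_violation(cx, cy, radius) <= 0:
                    centers.append((cx, cy))
                    placed = True
                    break
            if not placed:
                raise AnalysisError(
                    f"cannot place background ROI (diameter {dia} mm) at "
                    f"angle {math.degrees(ang):.0f} deg within margins")
        background[dia] = [CircleRoi(c, dia, k)
                           for k in slice_indices for c in centers]

    lung_rois = [CircleRoi(lung_center_mm, LUNG_ROI_DIAMETER_MM, k)
                 for k in slice_indices]
    return RoiSet(sphere_rois, background, lung_rois, actual_offsets)


def background_variability(volume: VolumeImage, rois: RoiSet) -> dict:
    """Per-size background mean c_B_j, SD_j (K-1 denominator over ROI
    means) and variability N_j."""
    out = {}
    for dia, roi_list in rois.background_rois.items():
        if len(roi_list) < 2:
            raise InputError("need >= 2 background ROIs per size")
        means = np.array([roi_mean(volume, r) for r in roi_list])
        c_b = float(means.mean())
        sd = float(means.std(ddof=1))
        if c_b == 0:
            raise AnalysisError("zero background mean")
        out[dia] = {"c_B": c_b, "SD": sd, "N_percent": 100.0 * sd / c_b,
                    "K": len(roi_list)}
    return out


def contrast_recovery(volume: VolumeImage, rois: RoiSet,
                      a_H_over_a_B: float = 8.0,
                      background: dict | None = None) -> list[dict]:
    """Hot/cold contrast recovery per sphere (Q_H / Q_C, percent)."""
    if a_H_over_a_B <= 1.0:
        raise InputError("hot-to-background activity ratio must exceed 1")
    background = background or background_variability(volume, rois)
    out = []
    for sp, roi in rois.sphere_rois:
        c = roi_mean(volume, roi)
        c_b = background[sp.diameter_mm]["c_B"]
        if c_b == 0:
            raise AnalysisError("zero background mean; contrast undefined")
        if sp.hot:
            q = (c / c_b - 1.0) / (a_H_over_a_B - 1.0) * 100.0
            out.append({"diameter_mm": sp.diameter_mm, "hot": True,
                        "Q_H_percent": q, "roi_mean": c})
        else:
            q = (1.0 - c / c_b) * 100.0
            out.append({"diameter_mm": sp.diameter_mm, "hot": False,
                        "Q_C_percent": q, "roi_mean": c})
    return out


def lung_error(volume: VolumeImage, rois: RoiSet,
               background: dict | None = None) -> dict:
    """Residual lung error per slice and its mean, percent of the 37 mm
    background mean."""
    background = background or background_variability(volume, rois)
    dia_max = max(rois.background_rois)
    c_b_ref = background[dia_max]["c_B"]
    if not rois.lung_rois:
        raise InputError("no lung ROIs placed")
    per_slice = [100.0 * roi_mean(volume, r) / c_b_ref
                 for r in rois.lung_rois]
    return {"per_slice_percent": per_slice,
            "summary_percent": float(np.mean(per_slice)),
            "reference_diameter_mm": dia_max}


def analyze_contrast(volume: VolumeImage, spheres: Sequence[SphereSpec],
                     a_H_over_a_B: float = 8.0,
                     lung_center_mm: tuple[float, float] = (0.0, 0.0),
                     wall_radius_mm: float = 147.0) -> dict:
    """Full IEC-phantom contrast pipeline on one reconstructed volume."""
    rois = place_rois(volume, spheres, lung_center_mm, wall_radius_mm)
    bg = background_variability(volume, rois)
    return {
        "contrast": contrast_recovery(volume, rois, a_H_over_a_B, bg),
        "background_variability": {
            str(d): v for d, v in bg.items()},
        "lung_error": lung_error(volume, rois, bg),
        "slice_offsets_mm": rois.slice_offsets_mm,
        "activity_ratio": a_H_over_a_B,
    }
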