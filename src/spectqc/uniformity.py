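"""Flood-field uniformity and defective-pixel accounting.

Adjacent detector pixels are summed into super-pixels (default 2x4 native
2.46 mm pixels -> 4.92 x 9.84 mm), a unit-sum 9-point smoothing kernel
(1,2,1; 2,4,2; 1,2,1)/16 is applied with edge renormalization, and the
integral / differential uniformities are computed over the useful and
central fields of view:

    IU = 100 * (max - min) / (max + min)            over the FOV mask
    DU = max over 5-super-pixel 1-D sliding windows of the IU statistic

For this pixelated column detector the UFOV is the full binned grid (no
Anger-style edge trimming) and the CFOV is the central 75 % of each UFOV
linear dimension, rounded inward to whole super-pixels.

Defective pixels are classified on the raw (unbinned) flood against the
detector median and grouped into 8-connected clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve, label

from .datatypes import AnalysisError, InputError, PlanarImage

__all__ = [
    "bin_pixels",
    "nema_smooth",
    "uniformity_metrics",
    "fov_mask",
    "defect_report",
    "UniformityResult",
    "DefectReport",
    "analyze_flood",
]

NEMA_KERNEL = np.array([[1.0, 2.0, 1.0],
                        [2.0, 4.0, 2.0],
                        [1.0, 2.0, 1.0]])
DU_WINDOW = 5          # super-pixels, NEMA standard
CFOV_FRACTION = 0.75


def bin_pixels(image: PlanarImage, factor: tuple[int, int] = (2, 4)
               ) -> PlanarImage:
    """Sum counts in non-overlapping blocks of ``factor`` pixels.

    Total counts are conserved exactly; the pixel pitch scales by the
    binning factors. Grid dimensions must divide evenly (no partial bins).
    """
    ft, fa = int(factor[0]), int(factor[1])
    if ft < 1 or fa < 1:
        raise InputError("binning factors must be >= 1")
    n0, n1 = image.counts.shape
    if n0 % ft or n1 % fa:
        raise InputError(
            f"grid {image.counts.shape} not divisible by factor {factor}")
    binned = image.counts.reshape(n0 // ft, ft, n1 // fa, fa).sum(axis=(1, 3))
    pitch = (image.pixel_pitch_mm[0] * ft, image.pixel_pitch_mm[1] * fa)
    return PlanarImage(binned, pitch, detector_id=image.detector_id,
                       duration_s=image.duration_s)


def nema_smooth(image: PlanarImage) -> PlanarImage:
    """9-point smoothing with the unit-sum (1,2,1;2,4,2;1,2,1) kernel.

    At edges the kernel is renormalized over its in-bounds weights, so no
    padding values are invented and a constant image stays constant.
    """
    if min(image.counts.shape) < 3:
        raise InputError("image must be at least 3x3 for smoothing")
    num = convolve(image.counts, NEMA_KERNEL, mode="constant", cval=0.0)
    den = convolve(np.ones_like(image.counts), NEMA_KERNEL,
                   mode="constant", cval=0.0)
    return PlanarImage(num / den, image.pixel_pitch_mm,
                       detector_id=image.detector_id,
                       duration_s=image.duration_s)


def fov_mask(shape: tuple[int, int], fov: str) -> np.ndarray:
    """Boolean mask of the requested field of view on the binned grid."""
    if fov == "UFOV":
        return np.ones(shape, dtype=bool)
    if fov != "CFOV":
        raise InputError("fov must be 'UFOV' or 'CFOV'")
    mask = np.zeros(shape, dtype=bool)
    keep = [max(1, int(np.floor(CFOV_FRACTION * n))) for n in shape]
    off = [(n - k) // 2 for n, k in zip(shape, keep)]
    mask[off[0]:off[0] + keep[0], off[1]:off[1] + keep[1]] = True
    return mask


def _iu(values: np.ndarray) -> float:
    vmax, vmin = float(values.max()), float(values.min())
    if vmax + vmin == 0:
        raise AnalysisError("all-zero field of view; uniformity undefined")
    return 100.0 * (vmax - vmin) / (vmax + vmin)


def uniformity_metrics(image: PlanarImage, fov: str = "UFOV",
                       exclude: np.ndarray | None = None
                       ) -> tuple[float, float]:
    """(integral_percent, differential_percent) over the FOV.

    ``image`` must already be binned and smoothed. ``exclude`` optionally
    masks out super-pixels (e.g. defect-dominated ones) from the
    statistics; differential windows containing an excluded super-pixel
    are skipped.
    """
    mask = fov_mask(image.counts.shape, fov)
    if exclude is not None:
        mask &= ~np.asarray(exclude, dtype=bool)
    if not mask.any():
        raise AnalysisError("empty field-of-view mask")
    iu = _iu(image.counts[mask])

    du = 0.0
    found = False
    for arr, msk in ((image.counts, mask), (image.counts.T, mask.T)):
        n_rows, n_cols = arr.shape
        for r in range(n_rows):
            for c in range(n_cols - DU_WINDOW + 1):
                if not msk[r, c:c + DU_WINDOW].all():
                    continue
                found = True
                du = max(du, _iu(arr[r, c:c + DU_WINDOW]))
    if not found:
        raise AnalysisError("no differential window fits inside the mask")
    return iu, du


@dataclass
class UniformityResult:
    """Per-detector and fleet flood-field uniformity."""

    per_detector: list[dict]

    def _stat(self, key: str) -> dict:
        vals = np.array([d[key] for d in self.per_detector])
        return {"highest": float(vals.max()),
                "range": [float(vals.min()), float(vals.max())]}

    def to_dict(self) -> dict:
        out = {"per_detector": self.per_detector}
        for key in ("iu_ufov_percent", "du_ufov_percent",
                    "iu_cfov_percent", "du_cfov_percent"):
            out[key] = self._stat(key)
        return out


@dataclass
class DefectReport:
    """Defective-pixel accounting for one raw flood image."""

    n_bad_pixels: int
    percent_good_pixels: float
    max_cluster_size: int
    bad_pixel_coordinates: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_bad_pixels": self.n_bad_pixels,
            "percent_good_pixels": self.percent_good_pixels,
            "max_cluster_size": self.max_cluster_size,
            "bad_pixel_coordinates": [list(c) for c in self.bad_pixel_coordinates],
        }


def defect_report(raw_image: PlanarImage, low_threshold: float = 0.7,
                  high_threshold: float = 1.3) -> DefectReport:
    """Classify defective pixels on the raw flood.

    A pixel is defective when counts / median(detector) falls outside
    ``[low_threshold, high_threshold]``; clusters are 8-connected
    components of defective pixels.
    """
    counts = raw_image.counts
    med = float(np.median(counts))
    if med == 0:
        raise InputError("median counts is zero; flood unusable")
    ratio = counts / med
    bad = (ratio < low_threshold) | (ratio > high_threshold)
    n_bad = int(bad.sum())
    labels, n_clusters = label(bad, structure=np.ones((3, 3), dtype=int))
    max_cluster = 0
    if n_clusters:
        max_cluster = int(np.bincount(labels.ravel())[1:].max())
    coords = [tuple(map(int, c)) for c in np.argwhere(bad)]
    return DefectReport(
        n_bad_pixels=n_bad,
        percent_good_pixels=100.0 * (1.0 - n_bad / counts.size),
        max_cluster_size=max_cluster,
        bad_pixel_coordinates=coords,
    )


def analyze_flood(raw_images: Sequence[PlanarImage],
                  bin_factor: tuple[int, int] = (2, 4),
                  defect_thresholds: tuple[float, float] = (0.7, 1.3),
                  defect_superpixel_fraction: float = 0.5,
                  ) -> tuple[UniformityResult, list[DefectReport]]:
    """Full flood pipeline per detector: defects on the raw image, then
    bin -> smooth -> IU/DU over UFOV and CFOV.

    Super-pixels whose raw-pixel content is at least
    ``defect_superpixel_fraction`` defective are excluded from the
    uniformity statistics.
    """
    per: list[dict] = []
    defects: list[DefectReport] = []
    for img in raw_images:
        rep = defect_report(img, *defect_thresholds)
        defects.append(rep)
        bad = np.zeros(img.counts.shape, dtype=bool)
        for r, c in rep.bad_pixel_coordinates:
            bad[r, c] = True
        binned_bad = bad.reshape(bad.shape[0] // bin_factor[0], bin_factor[0],
                                 bad.shape[1] // bin_factor[1], bin_factor[1]
                                 ).mean(axis=(1, 3))
        exclude = binned_bad >= defect_superpixel_fraction
        smoothed = nema_smooth(bin_pixels(img, bin_factor))
        iu_u, du_u = uniformity_metrics(smoothed, "UFOV", exclude)
        iu_c, du_c = uniformity_metrics(smoothed, "CFOV", exclude)
        per.append({
            "detector_id": img.detector_id,
            "iu_ufov_percent": iu_u, "du_ufov_percent": du_u,
            "iu_cfov_percent": iu_c, "du_cfov_percent": du_c,
        })
    return UniformityResult(per), defects
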