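"""Energy-resolution analysis per the NEMA NU 1-2018 procedure.

The photopeak maximum is located with a 3-point parabolic fit through the
maximum channel and its two neighbours; the FWHM (or FWTM) is the distance
between the half-height (tenth-height) crossings obtained by linear
interpolation of the channel values on each side of the peak. Fractional
energy resolution is the ratio FWHM / peak energy, as a percentage, per
detector column, with the fleet average and (min-max) range reported.

The same vertex + crossing estimator is reused, on millimetre grids, by
the spatial-resolution module (:mod:`spectqc.resolution`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datatypes import AnalysisError, InputError, Spectrum

__all__ = [
    "PeakFit",
    "parabolic_peak",
    "interpolated_width",
    "find_photopeak",
    "fwhm_by_interpolation",
    "energy_resolution",
    "EnergyResolutionResult",
]


# ---------------------------------------------------------------------------
# Generic 1-D peak estimator (shared with the resolution module)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakFit:
    """Parabolic vertex of a sampled peak."""

    position: float          # abscissa of the vertex (keV or mm)
    height: float            # vertex ordinate
    index: int               # raw maximum sample index
    flags: tuple[str, ...] = ()


def parabolic_peak(x: np.ndarray, y: np.ndarray,
                   min_significance: float = 5.0) -> PeakFit:
    """Vertex of the parabola through the maximum sample and its two
    neighbours on a uniform grid.

    The maximum must exceed the surrounding level by at least
    ``min_significance`` times its Poisson standard deviation; a flat
    window raises :class:`AnalysisError`. Plateau ties break to the lower
    index and are flagged; a vertex falling outside the 3-point support
    falls back to the raw maximum, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InputError("need >= 3 samples")
    i = int(np.argmax(y))
    flags: list[str] = []
    baseline = float(np.median(y))
    if y[i] - baseline < min_significance * np.sqrt(max(baseline, 1.0)):
        raise AnalysisError("no significant peak in window (flat)")
    if i == 0 or i == y.size - 1:
        raise AnalysisError("peak at window boundary")
    if y[i - 1] == y[i] or y[i + 1] == y[i]:
        flags.append("plateau_tie")
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    h = x[1] - x[0]
    if denom == 0.0:
        return PeakFit(float(x[i]), float(y[i]), i, tuple(flags + ["degenerate_fit"]))
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    if abs(delta) > 1.0:
        return PeakFit(float(x[i]), float(y[i]), i, tuple(flags + ["vertex_outside_support"]))
    xv = x[i] + delta * h
    yv = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return PeakFit(float(xv), float(yv), i, tuple(flags))


def interpolated_width(x: np.ndarray, y: np.ndarray, peak: PeakFit,
                       fraction: float = 0.5) -> float:
    """Width of the peak at ``fraction`` of the vertex height.

    On each side of the maximum sample the crossing nearest the peak is
    linearly interpolated between the two samples bracketing the
    threshold; the width is the right minus the left crossing, in the
    units of ``x``. ``fraction = 0.5`` gives the FWHM, ``0.1`` the FWTM.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0.0 < fraction < 1.0:
        raise InputError("fraction must be in (0, 1)")
    thr = fraction * peak.height
    i = peak.index

    def crossing(direction: int) -> float:
        j = i
        while True:
            j_next = j + direction
            if j_next < 0 or j_next >= y.size:
                raise AnalysisError(
                    "counts never fall below the threshold on one side; "
                    "width undefined")
            if y[j_next] < thr <= y[j]:
                frac = (y[j] - thr) / (y[j] - y[j_next])
                return float(x[j] + frac * (x[j_next] - x[j]))
            j = j_next

    left = crossing(-1)
    right = crossing(+1)
    return right - left


# ---------------------------------------------------------------------------
# Spectrum-level operations
# ---------------------------------------------------------------------------

DEFAULT_WINDOW_FRACTION = 0.15


def _window_slice(spectrum: Spectrum, window_keV: tuple[float, float]) -> slice:
    centers = spectrum.channel_centers
    idx = np.nonzero((centers >= window_keV[0]) & (centers <= window_keV[1]))[0]
    if idx.size < 7:
        raise InputError("analysis window must span >= 7 channels")
    return slice(int(idx[0]), int(idx[-1]) + 1)


def default_window(peak_keV: float,
                   fraction: float = DEFAULT_WINDOW_FRACTION
                   ) -> tuple[float, float]:
    """Default analysis window: photopeak energy +/- 15 %."""
    return (peak_keV * (1.0 - fraction), peak_keV * (1.0 + fraction))


def find_photopeak(spectrum: Spectrum,
                   search_window_keV: tuple[float, float]) -> PeakFit:
    """Locate the photopeak inside a search window.

    Returns the parabolic vertex (energy, height) plus bookkeeping; the
    vertex is guaranteed within one channel of the raw maximum.
    """
    sl = _window_slice(spectrum, search_window_keV)
    centers = spectrum.channel_centers[sl]
    counts = spectrum.counts[sl]
    fit = parabolic_peak(centers, counts)
    # re-express the raw-maximum index in full-spectrum coordinates
    return PeakFit(fit.position, fit.height, fit.index + sl.start, fit.flags)


def fwhm_by_interpolation(spectrum: Spectrum, peak: PeakFit,
                          fraction: float = 0.5) -> float:
    """FWHM (or, with ``fraction=0.1``, FWTM) of the photopeak in keV."""
    return interpolated_width(spectrum.channel_centers, spectrum.counts,
                              peak, fraction)


@dataclass
class EnergyResolutionResult:
    """Fleet energy-resolution summary for one isotope."""

    isotope: str
    peak_energy_keV: float          # mean vertex energy over detectors
    fwhm_keV: float                 # mean FWHM over detectors
    resolution_percent: float       # mean fractional resolution x 100
    resolution_range_percent: tuple[float, float]
    per_detector: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "isotope": self.isotope,
            "peak_energy_keV": self.peak_energy_keV,
            "fwhm_keV": self.fwhm_keV,
            "resolution_percent": self.resolution_percent,
            "resolution_range_percent": list(self.resolution_range_percent),
            "per_detector": self.per_detector,
        }


def energy_resolution(spectra: Sequence[Spectrum],
                      search_window_keV: tuple[float, float] | None = None,
                      nominal_peak_keV: float | None = None,
                      ) -> EnergyResolutionResult:
    """Per-detector fractional energy resolution plus fleet average/range.

    All spectra must share one isotope. The search window defaults to
    +/- 15 % around ``nominal_peak_keV`` (or, if that is not given, around
    each spectrum's raw maximum).
    """
    if not spectra:
        raise InputError("need at least one spectrum")
    isotopes = {s.isotope for s in spectra}
    if len(isotopes) > 1:
        raise InputError(f"mixed isotopes: {sorted(isotopes)}")
    per: list[dict] = []
    for s in spectra:
        if search_window_keV is not None:
            win = search_window_keV
        else:
            guess = nominal_peak_keV if nominal_peak_keV is not None else \
                float(s.channel_centers[np.argmax(s.counts)])
            win = default_window(guess)
        peak = find_photopeak(s, win)
        fwhm = fwhm_by_interpolation(s, peak)
        per.append({
            "detector_id": s.detector_id,
            "peak_energy_keV": peak.position,
            "fwhm_keV": fwhm,
            "resolution_percent": 100.0 * fwhm / peak.position,
            "flags": list(peak.flags),
        })
    res = np.array([d["resolution_percent"] for d in per])
    return EnergyResolutionResult(
        isotope=next(iter(isotopes)),
        peak_energy_keV=float(np.mean([d["peak_energy_keV"] for d in per])),
        fwhm_keV=float(np.mean([d["fwhm_keV"] for d in per])),
        resolution_percent=float(res.mean()),
        resolution_range_percent=(float(res.min()), float(res.max())),
        per_detector=per,
    )
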