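"""Core in-memory containers shared by the simulation and analysis stages.

Coordinate convention (used everywhere): right-handed grids in millimetres,
axial direction = third axis (Z), voxel/pixel centres at
``(index + 0.5) * spacing`` with 0-based indices.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

LN2 = math.log(2.0)

#: Tc-99m half-life in seconds (mean lifetime tau = 31198.6 s).
T_HALF_TC99M_S = 21625.2

#: Half-lives of the isotopes used in the acceptance tests, seconds.
HALF_LIFE_S = {
    "Tc99m": T_HALF_TC99M_S,
    "Co57": 271.79 * 86400.0,
    "I123": 13.2234 * 3600.0,
}

#: Effective collimator septal length for the distance-extrapolation
#: formula, millimetres, by isotope.
L_EFF_MM = {"Tc99m": 17.72}

#: Conversion between a Gaussian sigma and its full width at half maximum.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * LN2)  # 2.3548...

#: Ratio of a Gaussian's tenth-max width to its half-max width.
FWTM_OVER_FWHM = math.sqrt(math.log(10.0) / LN2)  # 1.8226...


class InputError(ValueError):
    """A precondition on user-supplied input was violated."""


class AnalysisError(RuntimeError):
    """An analysis step could not produce a defined result."""


def mean_lifetime(half_life_s: float) -> float:
    """tau = T_half / ln 2."""
    if half_life_s <= 0:
        raise InputError("half-life must be positive")
    return half_life_s / LN2


@dataclass(frozen=True)
class DetectorGeometry:
    """Pixel layout of one detector column.

    Defaults describe a CZT column of 7 stacked 16x16 modules with a
    2.46 mm pixel pitch (16 pixels transaxial x 112 axial, 27.5 cm axial
    coverage), twelve such columns forming the ring.
    """

    pixel_pitch_mm: float = 2.46
    pixels_transaxial: int = 16
    modules_axial: int = 7
    pixels_per_module_axial: int = 16
    n_columns: int = 12

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise InputError("pixel pitch must be positive")
        for name in ("pixels_transaxial", "modules_axial",
                     "pixels_per_module_axial", "n_columns"):
            if getattr(self, name) < 1:
                raise InputError(f"{name} must be >= 1")

    @property
    def pixels_axial(self) -> int:
        return self.modules_axial * self.pixels_per_module_axial

    @property
    def shape(self) -> tuple[int, int]:
        """(transaxial, axial) pixel counts."""
        return (self.pixels_transaxial, self.pixels_axial)

    @property
    def axial_extent_mm(self) -> float:
        return self.pixels_axial * self.pixel_pitch_mm


@dataclass
class GroundTruth:
    """Free-form record of the parameters a generator drew its output from.

    Everything a downstream parameter-recovery test needs (true FWHM
    fraction, gain map, defect mask, sensitivity factors, sphere ratios,
    line positions, ...) is stored here by the generator that made the
    data. Values must survive a JSON round-trip unchanged.
    """

    params: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    def __contains__(self, key: str) -> bool:
        return key in self.params

    def get(self, key: str, default: Any = None) -> Any:
        return self.params.get(key, default)

    def to_json(self) -> str:
        return json.dumps(self.params, sort_keys=True, default=_jsonify)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(params=json.loads(text))


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")


@dataclass
class Spectrum:
    """Channelized energy histogram.

    ``channel_edges`` are the ``n+1`` uniform bin edges in keV (width 0.5
    keV in the low-energy front-end mode, 1 keV in the medium-energy mode);
    ``counts`` the per-channel counts.
    """

    channel_edges: np.ndarray
    counts: np.ndarray
    isotope: str = ""
    detector_id: str = ""

    def __post_init__(self) -> None:
        self.channel_edges = np.asarray(self.channel_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.channel_edges.ndim != 1 or self.counts.ndim != 1:
            raise InputError("spectrum arrays must be 1-D")
        if self.channel_edges.size != self.counts.size + 1:
            raise InputError("need n+1 channel edges for n count bins")
        widths = np.diff(self.channel_edges)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-9):
            raise InputError("channel width must be uniform")
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")

    @property
    def channel_keV(self) -> float:
        return float(self.channel_edges[1] - self.channel_edges[0])

    @property
    def channel_centers(self) -> np.ndarray:
        return 0.5 * (self.channel_edges[:-1] + self.channel_edges[1:])


@dataclass
class PlanarImage:
    """2-D count grid from one detector column.

    ``counts`` is indexed ``[transaxial, axial]``; ``pixel_pitch_mm`` is the
    (transaxial, axial) pitch, which differs after super-pixel binning.
    """

    counts: np.ndarray
    pixel_pitch_mm: tuple[float, float] = (2.46, 2.46)
    detector_id: str = ""
    duration_s: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise InputError("planar image must be 2-D")
        if np.any(self.counts < 0):
            raise InputError("counts must be non-negative")
        if min(self.pixel_pitch_mm) <= 0:
            raise InputError("pixel pitch must be positive")


@dataclass
class VolumeImage:
    """Reconstructed 3-D count grid (X, Y, Z) with voxel spacing in mm."""

    counts: np.ndarray
    voxel_mm: tuple[float, float, float] = (2.46, 2.46, 2.46)
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 3:
            raise InputError("volume must be 3-D")
        if min(self.voxel_mm) <= 0:
            raise InputError("voxel spacing must be positive")

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along ``axis``,
        origin at the volume centre."""
        n = self.counts.shape[axis]
        sp = self.voxel_mm[axis]
        return (np.arange(n) + 0.5) * sp - 0.5 * n * sp


@dataclass
class CountRatePoint:
    t_start_s: float
    dt_s: float
    counts: float


@dataclass
class CountRateSeries:
    """Ordered timed count measurements from a decaying source."""

    points: list[CountRatePoint]
    background_cps: float = 0.0
    half_life_s: float = T_HALF_TC99M_S
    isotope: str = "Tc99m"

    def __post_init__(self) -> None:
        t = np.array([p.t_start_s for p in self.points])
        dt = np.array([p.dt_s for p in self.points])
        k = np.array([p.counts for p in self.points])
        if t.size and np.any(np.diff(t) <= 0):
            raise InputError("start times must be strictly increasing")
        if np.any(dt <= 0):
            raise InputError("elapsed times must be positive")
        if np.any(k < 0):
            raise InputError("counts must be non-negative")
        if self.background_cps < 0:
            raise InputError("background rate must be non-negative")
        self.tau_s = mean_lifetime(self.half_life_s)

    def __len__(self) -> int:
        return len(self.points)


def rng_from_seed(seed: int | None) -> np.random.Generator:
    """One explicit generator per call; no global state."""
    return np.random.default_rng(seed)


def as_mapping(obj: Mapping[str, Any] | None) -> dict[str, Any]:
    return dict(obj) if obj else {}
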