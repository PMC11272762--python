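"""Planar and volume sensitivity with detector-detector variation.

Planar sensitivity: a calibrated source (activity ``A_cal`` at time
``T_cal``) is imaged at 150 mm; the decay-corrected count rate is

    R = (C / tau) * exp((T_150 - T_cal) / tau) / (1 - exp(-T_acq / tau))

(decay from calibration to acquisition *start*, with the last factor
handling in-acquisition decay), and the per-detector sensitivity is
``S = R / A_cal`` in cps/MBq.

Volume sensitivity: from the twelve per-detector summed cylinder images,
``SVS = A / B_c`` (average counts per second over the activity
concentration decay-corrected to the acquisition midpoint),
``VSAC = SVS / Length`` per axial centimetre, and the detector-detector
spread ``DDS = 100 * (c_max - c_min) / c_max``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import AnalysisError, InputError, T_HALF_TC99M_S, mean_lifetime

__all__ = [
    "SensitivityMeasurement",
    "decay_corrected_rate",
    "planar_sensitivity",
    "volume_sensitivity",
    "VolumeSensitivityResult",
]


@dataclass(frozen=True)
class SensitivityMeasurement:
    """One detector's static acquisition of a calibrated source.

    Times are seconds on a common clock; ``T_150`` is the acquisition
    start, ``T_cal`` the activity calibration time.
    """

    A_cal_MBq: float
    T_cal_s: float
    T_150_s: float
    T_acq_150_s: float
    C_D150: float
    half_life_s: float = T_HALF_TC99M_S
    detector_id: str = ""

    def __post_init__(self) -> None:
        if self.A_cal_MBq <= 0:
            raise InputError("calibration activity must be positive")
        if self.T_150_s < self.T_cal_s:
            raise InputError("acquisition cannot precede calibration")
        if self.T_acq_150_s <= 0:
            raise InputError("acquisition duration must be positive")
        if self.C_D150 < 0:
            raise InputError("counts must be non-negative")


def decay_corrected_rate(m: SensitivityMeasurement) -> float:
    """Decay-corrected total count rate referred to the calibration time."""
    tau = mean_lifetime(m.half_life_s)
    return (m.C_D150 / tau
            * math.exp((m.T_150_s - m.T_cal_s) / tau)
            / -math.expm1(-m.T_acq_150_s / tau))


def planar_sensitivity(measurements: Sequence[SensitivityMeasurement]
                       ) -> dict:
    """Per-detector sensitivity S = R / A_cal plus fleet average/range."""
    if not measurements:
        raise InputError("need at least one measurement")
    a_cals = {m.A_cal_MBq for m in measurements}
    if len(a_cals) > 1:
        raise InputError("all measurements must share one calibrated source")
    per = []
    for m in measurements:
        r = decay_corrected_rate(m)
        per.append({
            "detector_id": m.detector_id,
            "rate_cps": r,
            "sensitivity_cps_per_MBq": r / m.A_cal_MBq,
        })
    s = np.array([d["sensitivity_cps_per_MBq"] for d in per])
    return {
        "per_detector": per,
        "average_cps_per_MBq": float(s.mean()),
        "range_cps_per_MBq": [float(s.min()), float(s.max())],
    }


@dataclass
class VolumeSensitivityResult:
    """Volume-sensitivity metrics from a uniform-cylinder acquisition."""

    svs_cps_cc_per_MBq: float
    vsac_cps_cc_per_MBq_per_cm: float
    dds_percent: float
    average_rate_cps: float
    concentration_at_mid_MBq_per_cc: float
    length_cm: float
    per_detector_counts: list[float]

    def to_dict(self) -> dict:
        return {
            "SVS_cps_cc_per_MBq": self.svs_cps_cc_per_MBq,
            "SVS_kcps_cc_per_MBq": self.svs_cps_cc_per_MBq / 1e3,
            "VSAC_cps_cc_per_MBq_per_cm": self.vsac_cps_cc_per_MBq_per_cm,
            "DDS_percent": self.dds_percent,
            "average_rate_cps": self.average_rate_cps,
            "B_c_MBq_per_cc_at_midpoint": self.concentration_at_mid_MBq_per_cc,
            "length_cm": self.length_cm,
            "per_detector_counts": self.per_detector_counts,
            # the per-centimetre figure follows SVS / Length; the unit
            # string kcps*MBq^-1*cm^-2 sometimes quoted for it is
            # dimensionally inconsistent with that definition
            "unit_note": "VSAC = SVS / axial length (cps*cc/(MBq*cm))",
        }


def volume_sensitivity(per_detector_counts: Sequence[float],
                       duration_s: float,
                       activity_conc_at_cal_MBq_per_cc: float,
                       T_cal_s: float,
                       T_mid_s: float,
                       half_life_s: float = T_HALF_TC99M_S,
                       length_cm: float = 20.0) -> VolumeSensitivityResult:
    """SVS, VSAC and DDS from per-detector summed totals.

    ``T_mid_s`` is the time halfway through the SPECT acquisition, to
    which the activity concentration is decay-corrected.
    """
    c = np.asarray(per_detector_counts, dtype=float)
    if c.size < 2:
        raise InputError("need >= 2 detector totals")
    if duration_s <= 0 or length_cm <= 0:
        raise InputError("duration and length must be positive")
    if activity_conc_at_cal_MBq_per_cc <= 0:
        raise InputError("activity concentration must be positive")
    if c.max() == 0:
        raise AnalysisError("all detector totals zero; DDS undefined")
    tau = mean_lifetime(half_life_s)
    a = c.sum() / duration_s
    b_c = activity_conc_at_cal_MBq_per_cc * math.exp(-(T_mid_s - T_cal_s) / tau)
    svs = a / b_c
    return VolumeSensitivityResult(
        svs_cps_cc_per_MBq=svs,
        vsac_cps_cc_per_MBq_per_cm=svs / length_cm,
        dds_percent=100.0 * (c.max() - c.min()) / c.max(),
        average_rate_cps=a,
        concentration_at_mid_MBq_per_cc=b_c,
        length_cm=length_cm,
        per_detector_counts=c.tolist(),
    )
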