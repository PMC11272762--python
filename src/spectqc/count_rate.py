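"""Count-rate performance by the decay-source method.

A single source decays through the system's full rate range while timed
static acquisitions are recorded. Each measurement is background-
corrected, converted to an observed count rate with a decay-during-
acquisition correction, and the input (true, loss-free) count rate is
extrapolated from a late low-rate reference measurement where losses are
negligible:

    C_i   = K_i - R_bkg * dt_i
    OCR_i = C_i / (tau * (1 - exp(-dt_i / tau)))
    ICR_i = OCR_n * exp((t_n - t_i) / tau)

with tau the mean lifetime (half-life / ln 2) and n the reference index.
The curve readouts are the maximum observed rate and the input rate at
20 % loss (where OCR / ICR crosses 0.8).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import AnalysisError, CountRateSeries, InputError

__all__ = [
    "net_counts",
    "observed_rate",
    "input_rate",
    "rate_curve",
    "RateCurve",
]

#: Observed rate below which a measurement is treated as loss-free and may
#: serve as the extrapolation reference.
LOSS_FREE_OCR_CPS = 10_000.0


def net_counts(counts: float, dt_s: float, background_cps: float
               ) -> tuple[float, bool]:
    """Background-corrected counts ``C = K - R_bkg * dt``.

    Negative results are clipped to zero; the returned flag reports
    whether clipping occurred.
    """
    if counts < 0 or background_cps < 0 or dt_s <= 0:
        raise InputError("counts and rates must be non-negative, dt positive")
    c = counts - background_cps * dt_s
    if c < 0:
        return 0.0, True
    return c, False


def observed_rate(net: float, dt_s: float, tau_s: float) -> float:
    """Decay-corrected observed count rate at the acquisition start."""
    if dt_s <= 0 or tau_s <= 0:
        raise InputError("dt and tau must be positive")
    return net / (tau_s * -math.expm1(-dt_s / tau_s))


def input_rate(ocr_ref: float, t_ref_s: float, t_s: float, tau_s: float
               ) -> float:
    """Loss-free input rate extrapolated from the reference measurement."""
    if tau_s <= 0:
        raise InputError("tau must be positive")
    return ocr_ref * math.exp((t_ref_s - t_s) / tau_s)


@dataclass
class RateCurve:
    """Observed-vs-input count-rate curve and its NEMA readouts."""

    icr_cps: np.ndarray
    ocr_cps: np.ndarray
    reference_index: int
    max_ocr_cps: float
    icr_at_20pct_loss_cps: float | None
    flags: list[str] = field(default_factory=list)
    clipped: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "icr_cps": self.icr_cps.tolist(),
            "ocr_cps": self.ocr_cps.tolist(),
            "reference_index": self.reference_index,
            "max_ocr_cps": self.max_ocr_cps,
            "icr_at_20pct_loss_cps": self.icr_at_20pct_loss_cps,
            "flags": self.flags,
            "clipped_points": self.clipped,
        }


def _select_reference(ocr: np.ndarray) -> tuple[int, list[str]]:
    """Latest (lowest-rate) point with OCR below the loss-free threshold;
    if none qualifies, the last point, flagged."""
    low = np.nonzero(ocr < LOSS_FREE_OCR_CPS)[0]
    if low.size:
        return int(low[-1]), []
    return int(ocr.size - 1), ["no_loss_free_reference"]


def rate_curve(series: CountRateSeries,
               loss_fraction: float = 0.2,
               require_20pct_loss: bool = True) -> RateCurve:
    """Apply the three-step pipeline to a series and read the curve.

    The 20 %-loss input rate is found by linearly interpolating the
    OCR/ICR ratio against log ICR between the two bracketing points
    (highest-ICR crossing when several exist). Points where noise pushes
    OCR above ICR are retained in the curve but excluded from the
    crossing search. When the ratio never crosses the loss level an
    :class:`AnalysisError` is raised (or, with ``require_20pct_loss``
    false, the readout is ``None`` and the curve flagged); if no
    saturation plateau is seen the maximum is flagged as censored.
    """
    if len(series) < 5:
        raise InputError("need >= 5 measurements spanning the rate range")
    t = np.array([p.t_start_s for p in series.points])
    dt = np.array([p.dt_s for p in series.points])
    k = np.array([p.counts for p in series.points])
    tau = series.tau_s

    clipped: list[int] = []
    net = np.empty_like(k)
    for i in range(k.size):
        net[i], was_clipped = net_counts(k[i], dt[i], series.background_cps)
        if was_clipped:
            clipped.append(i)
    ocr = np.array([observed_rate(c, d, tau) for c, d in zip(net, dt)])

    ref, flags = _select_reference(ocr)
    icr = np.array([input_rate(ocr[ref], t[ref], ti, tau) for ti in t])

    max_ocr = float(ocr.max())
    # censoring check: the curve should flatten near its maximum
    order = np.argsort(icr)
    top_ocr = ocr[order][-2:]
    if top_ocr.size == 2 and top_ocr[0] < 0.99 * top_ocr[1]:
        flags.append("max_ocr_censored")

    threshold = 1.0 - loss_fraction
    ratio = ocr / icr
    valid = ratio <= 1.0 + 1e-9   # noise can push OCR above ICR
    x = np.log(icr[order])
    r = ratio[order]
    v = valid[order]
    crossing = None
    for j in range(x.size - 1, 0, -1):   # highest-ICR crossing first
        if not (v[j] and v[j - 1]):
            continue
        r_lo, r_hi = r[j - 1], r[j]      # lo/hi in ICR
        if (r_lo - threshold) * (r_hi - threshold) <= 0 and r_lo != r_hi:
            frac = (threshold - r_lo) / (r_hi - r_lo)
            crossing = float(np.exp(x[j - 1] + frac * (x[j] - x[j - 1])))
            break
    if crossing is None:
        flags.append("loss_crossing_not_found")
        if require_20pct_loss:
            raise AnalysisError(
                f"OCR/ICR never crosses {threshold}; loss readout undefined")

    return RateCurve(icr_cps=icr, ocr_cps=ocr, reference_index=ref,
                     max_ocr_cps=max_ocr, icr_at_20pct_loss_cps=crossing,
                     flags=flags, clipped=clipped)
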