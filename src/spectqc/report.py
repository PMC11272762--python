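"""Structured QC reports and pass/fail evaluation.

A :class:`QCReport` collects the per-test result blocks produced by the
analysis modules plus run metadata; :func:`evaluate` compares selected
metrics against a :class:`ToleranceSet` (daily-QC limits are
configuration, not code — the defaults mirror a manufacturer tolerance
table: DU < 3.6 %, IU < 4.5 %, energy resolution < 7.5 %, peak position
120.6-123.6 keV, good pixels 93.8-100 %, cluster size < 8) and emits
PASS / FAIL / NOT-EVALUATED verdicts, each citing the limit that
produced it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any

import numpy as np

from .datatypes import InputError

__all__ = ["Tolerance", "ToleranceSet", "QCReport", "evaluate",
           "DEFAULT_TOLERANCES"]

SCHEMA_VERSION = 1

#: Display rounding per metric family (decimal places).
DISPLAY_DECIMALS = {"percent": 2, "mm": 2, "keV": 1, "cps": 1, "count": 0}


@dataclass(frozen=True)
class Tolerance:
    """One named limit: comparator '<', '<=', '>', '>=' or 'range'."""

    metric: str
    comparator: str
    limit: float | tuple[float, float]
    units: str = ""

    def check(self, value: float) -> bool:
        if self.comparator == "<":
            return value < self.limit
        if self.comparator == "<=":
            return value <= self.limit
        if self.comparator == ">":
            return value > self.limit
        if self.comparator == ">=":
            return value >= self.limit
        if self.comparator == "range":
            lo, hi = self.limit  # type: ignore[misc]
            return lo <= value <= hi
        raise InputError(f"bad comparator {self.comparator!r}")

    def describe(self) -> str:
        if self.comparator == "range":
            lo, hi = self.limit  # type: ignore[misc]
            return f"{lo}-{hi} {self.units}".strip()
        return f"{self.comparator} {self.limit} {self.units}".strip()


class ToleranceSet(dict):
    """Mapping metric name -> :class:`Tolerance`."""

    @classmethod
    def from_mapping(cls, mapping: dict[str, Any]) -> "ToleranceSet":
        out = cls()
        for name, spec in mapping.items():
            limit = spec["limit"]
            if isinstance(limit, (list, tuple)):
                limit = (float(limit[0]), float(limit[1]))
            else:
                limit = float(limit)
            out[name] = Tolerance(name, spec["comparator"], limit,
                                  spec.get("units", ""))
        return out


DEFAULT_TOLERANCES = ToleranceSet.from_mapping({
    "differential_uniformity_percent": {"comparator": "<", "limit": 3.6, "units": "%"},
    "integral_uniformity_percent": {"comparator": "<", "limit": 4.5, "units": "%"},
    "energy_resolution_percent": {"comparator": "<", "limit": 7.5, "units": "%"},
    "peak_position_keV": {"comparator": "range", "limit": (120.6, 123.6), "units": "keV"},
    "good_pixels_percent": {"comparator": "range", "limit": (93.8, 100.0), "units": "%"},
    "max_cluster_size": {"comparator": "<", "limit": 8, "units": "pixels"},
})


def _display(value: Any) -> Any:
    if isinstance(value, float):
        return round(value, 4)
    return value


@dataclass
class QCReport:
    """Container for a full QC session's results and verdicts."""

    results: dict[str, Any] = field(default_factory=dict)
    metadata: dict[str, Any] = field(default_factory=dict)
    verdicts: list[dict] = field(default_factory=list)

    def add(self, name: str, block: Any) -> None:
        if hasattr(block, "to_dict"):
            block = block.to_dict()
        self.results[name] = block

    def to_dict(self, timestamp: bool = True) -> dict:
        meta = dict(self.metadata)
        meta.setdefault("schema_version", SCHEMA_VERSION)
        if timestamp:
            meta.setdefault("generated_utc",
                            datetime.now(timezone.utc).isoformat())
        return {"metadata": meta, "results": _sanitize(self.results),
                "verdicts": self.verdicts}

    def to_json(self, timestamp: bool = True) -> str:
        return json.dumps(self.to_dict(timestamp=timestamp), indent=2,
                          sort_keys=True)


def _sanitize(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def evaluate(report: QCReport, metrics: dict[str, float],
             tolerances: ToleranceSet | None = None) -> list[dict]:
    """Compare measured metrics against tolerances.

    ``metrics`` maps tolerance names to measured values; a metric listed
    in the tolerance set but absent from ``metrics`` (or None) is marked
    NOT-EVALUATED, never PASS. Verdicts are appended to the report and
    returned.
    """
    tolerances = tolerances if tolerances is not None else DEFAULT_TOLERANCES
    verdicts = []
    for name, tol in tolerances.items():
        value = metrics.get(name)
        if value is None:
            verdict = "NOT-EVALUATED"
        else:
            verdict = "PASS" if tol.check(float(value)) else "FAIL"
        verdicts.append({
            "metric": name,
            "value": _sanitize(value),
            "display": _display(value),
            "limit": tol.describe(),
            "verdict": verdict,
        })
    report.verdicts.extend(verdicts)
    return verdicts
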