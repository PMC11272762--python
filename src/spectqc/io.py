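"""Fixture and DICOM readers/writers.

Fixtures are HDF5 files (datasets ``counts`` plus spacing/metadata
attributes) with an optional JSON sidecar (``<path>.truth.json``)
mirroring the generator's ground truth. Spectra and count-rate series can
also round-trip through plain CSV with ``#``-prefixed metadata lines.
DICOM support is read-only and minimal: spacing, counts, duration and
identifiers are taken from their standard tags and missing tags fail
loudly rather than being defaulted.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import (
    CountRatePoint,
    CountRateSeries,
    GroundTruth,
    InputError,
    PlanarImage,
    Spectrum,
    VolumeImage,
)

__all__ = [
    "save_planar", "save_volume", "save_spectrum",
    "read_planar", "read_volume", "read_spectrum",
    "save_spectrum_csv", "read_spectrum_csv",
    "save_series_csv", "read_series_csv",
    "save_truth", "read_truth",
    "read_dicom_volume",
]


def _truth_path(path: str | Path) -> Path:
    return Path(str(path) + ".truth.json")


def save_truth(path: str | Path, truth: GroundTruth) -> None:
    _truth_path(path).write_text(truth.to_json())


def read_truth(path: str | Path) -> GroundTruth | None:
    p = _truth_path(path)
    if not p.exists():
        return None
    return GroundTruth.from_json(p.read_text())


def save_planar(path: str | Path, image: PlanarImage,
                truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=image.counts)
        f.attrs["kind"] = "planar"
        f.attrs["pixel_pitch_mm"] = image.pixel_pitch_mm
        f.attrs["detector_id"] = image.detector_id
        f.attrs["duration_s"] = image.duration_s
    if truth is not None:
        save_truth(path, truth)


def read_planar(path: str | Path) -> PlanarImage:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "planar":
            raise InputError(f"{path} is not a planar fixture")
        if "pixel_pitch_mm" not in f.attrs:
            raise InputError("missing attribute pixel_pitch_mm")
        return PlanarImage(
            f["counts"][()],
            tuple(np.asarray(f.attrs["pixel_pitch_mm"], dtype=float)),
            detector_id=str(f.attrs.get("detector_id", "")),
            duration_s=float(f.attrs.get("duration_s", 0.0)),
        )


def save_volume(path: str | Path, volume: VolumeImage,
                truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=volume.counts)
        f.attrs["kind"] = "volume"
        f.attrs["voxel_mm"] = volume.voxel_mm
        f.attrs["annotations"] = json.dumps(volume.annotations, default=str)
    if truth is not None:
        save_truth(path, truth)


def read_volume(path: str | Path) -> VolumeImage:
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "volume":
            raise InputError(f"{path} is not a volume fixture")
        if "voxel_mm" not in f.attrs:
            raise InputError("missing attribute voxel_mm")
        return VolumeImage(
            f["counts"][()],
            tuple(np.asarray(f.attrs["voxel_mm"], dtype=float)),
            annotations=json.loads(str(f.attrs.get("annotations", "{}"))),
        )


def save_spectrum(path: str | Path, spectrum: Spectrum,
                  truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=spectrum.counts)
        f.create_dataset("channel_edges", data=spectrum.channel_edges)
        f.attrs["kind"] = "spectrum"
        f.attrs["isotope"] = spectrum.isotope
        f.attrs["detector_id"] = spectrum.detector_id
    if truth is not None:
        save_truth(path, truth)


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return read_spectrum_csv(path)
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "spectrum":
            raise InputError(f"{path} is not a spectrum fixture")
        return Spectrum(
            f["channel_edges"][()], f["counts"][()],
            isotope=str(f.attrs.get("isotope", "")),
            detector_id=str(f.attrs.get("detector_id", "")),
        )


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------

def _read_csv_with_meta(path: str | Path) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    from io import StringIO
    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return df, meta


def save_spectrum_csv(path: str | Path, spectrum: Spectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# isotope: {spectrum.isotope}\n")
        fh.write(f"# detector_id: {spectrum.detector_id}\n")
        pd.DataFrame({"channel_keV": spectrum.channel_centers,
                      "counts": spectrum.counts}).to_csv(fh, index=False)


def read_spectrum_csv(path: str | Path) -> Spectrum:
    df, meta = _read_csv_with_meta(path)
    centers = df["channel_keV"].to_numpy(dtype=float)
    widths = np.diff(centers)
    if widths.size == 0:
        raise InputError("spectrum CSV needs >= 2 channels")
    if not np.allclose(widths, widths[0], rtol=1e-9, atol=1e-9):
        raise InputError("non-uniform channel grid in spectrum CSV")
    w = widths[0]
    edges = np.concatenate([[centers[0] - 0.5 * w], centers + 0.5 * w])
    return Spectrum(edges, df["counts"].to_numpy(dtype=float),
                    isotope=meta.get("isotope", ""),
                    detector_id=meta.get("detector_id", ""))


def save_series_csv(path: str | Path, series: CountRateSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# background_cps: {series.background_cps}\n")
        fh.write(f"# half_life_s: {series.half_life_s}\n")
        fh.write(f"# isotope: {series.isotope}\n")
        pd.DataFrame({
            "t_start_s": [p.t_start_s for p in series.points],
            "dt_s": [p.dt_s for p in series.points],
            "counts": [p.counts for p in series.points],
        }).to_csv(fh, index=False)


def read_series_csv(path: str | Path) -> CountRateSeries:
    df, meta = _read_csv_with_meta(path)
    for key in ("background_cps", "half_life_s"):
        if key not in meta:
            raise InputError(f"series CSV missing metadata line '# {key}:'")
    pts = [CountRatePoint(float(r.t_start_s), float(r.dt_s), float(r.counts))
           for r in df.itertuples()]
    return CountRateSeries(pts,
                           background_cps=float(meta["background_cps"]),
                           half_life_s=float(meta["half_life_s"]),
                           isotope=meta.get("isotope", ""))


# ---------------------------------------------------------------------------
# DICOM (read-only, tag-driven)
# ---------------------------------------------------------------------------

def read_dicom_volume(path: str | Path) -> VolumeImage:
    """Read a reconstructed volume from a single multi-frame DICOM file.

    Requires PixelSpacing and either SpacingBetweenSlices or
    SliceThickness; any absent tag raises an error naming it.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    if "PixelSpacing" not in ds:
        raise InputError("DICOM missing PixelSpacing")
    dy, dx = (float(v) for v in ds.PixelSpacing)
    if "SpacingBetweenSlices" in ds:
        dz = float(ds.SpacingBetweenSlices)
    elif "SliceThickness" in ds:
        dz = float(ds.SliceThickness)
    else:
        raise InputError("DICOM missing SpacingBetweenSlices/SliceThickness")
    arr = ds.pixel_array.astype(float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise InputError("expected a 2-D or 3-D DICOM pixel array")
    # DICOM frames are (frame, row, col) = (z, y, x); our volumes are (x, y, z)
    counts = np.transpose(arr, (2, 1, 0))
    return VolumeImage(counts, (dx, dy, dz),
                       annotations={"source": "dicom",
                                    "sop_class": str(getattr(ds, "SOPClassUID", ""))})
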