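"""File I/O for films, phantom images, profiles, spectra and traces.

Rasters are written as 16-bit grayscale TIFF with a JSON sidecar carrying
the pixel spacing, origin, units, the uint16 scaling and any generator
ground truth; profiles, spectra and motion traces are plain CSV.
Single-frame DICOM images can be read (pixel spacing honoured).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import BeamProfile, DoseImage, GrayImage, MotionTrace, SpectrumProfile

__all__ = [
    "write_image",
    "read_image",
    "read_dicom_image",
    "write_profile",
    "read_profile",
    "write_spectrum",
    "read_spectrum",
    "write_trace",
    "read_trace",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(path, image: DoseImage, ground_truth: dict | None = None) -> None:
    """Write a raster as 16-bit TIFF plus a JSON geometry sidecar."""
    path = Path(path)
    vmax = float(image.values.max())
    scale = vmax / 65535.0 if vmax > 0 else 1.0
    raw = np.round(image.values / scale).astype(np.uint16) if vmax > 0 else np.zeros(
        image.values.shape, np.uint16
    )
    tifffile.imwrite(path, raw)
    meta = {
        "pixel_spacing_mm": image.pixel_spacing_mm,
        "origin_mm": list(image.origin_mm),
        "units": image.units,
        "scale": scale,
    }
    if ground_truth:
        meta["ground_truth"] = ground_truth
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_image(path) -> DoseImage:
    """Read a TIFF written by :func:`write_image` (sidecar required)."""
    path = Path(path)
    raw = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return DoseImage(
        raw * meta.get("scale", 1.0),
        meta["pixel_spacing_mm"],
        tuple(meta.get("origin_mm", (0.0, 0.0))),
        meta.get("units", "dose"),
    )


def read_dicom_image(path) -> GrayImage:
    """Read a single-frame DICOM image; PixelSpacing is honoured."""
    import pydicom

    ds = pydicom.dcmread(path)
    spacing = float(ds.PixelSpacing[0]) if "PixelSpacing" in ds else 1.0
    vals = ds.pixel_array.astype(float)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return GrayImage(vals * slope + intercept, spacing, units="raw")


def write_profile(path, profile: BeamProfile) -> None:
    pd.DataFrame({"position_cm": profile.positions_cm, "value": profile.values}).to_csv(
        path, index=False
    )


def read_profile(path, axis: str = "cross_plane") -> BeamProfile:
    df = pd.read_csv(path)
    return BeamProfile(df["position_cm"].to_numpy(), df["value"].to_numpy(), axis=axis)


def write_spectrum(path, spectrum: SpectrumProfile) -> None:
    pd.DataFrame(
        {"frequency_hz": spectrum.frequency_hz, "magnitude": spectrum.magnitude}
    ).to_csv(path, index=False)


def read_spectrum(path, nominal_f0_hz: float | None = None) -> SpectrumProfile:
    df = pd.read_csv(path)
    kwargs = {} if nominal_f0_hz is None else {"nominal_f0_hz": nominal_f0_hz}
    return SpectrumProfile(df["frequency_hz"].to_numpy(), df["magnitude"].to_numpy(), **kwargs)


def write_trace(path, trace: MotionTrace) -> None:
    pd.DataFrame(
        {
            "time_s": trace.time_s,
            "position_mm": trace.position_mm,
            "beam_on": trace.beam_on.astype(int),
        }
    ).to_csv(path, index=False)


def read_trace(path, meta: dict | None = None) -> MotionTrace:
    df = pd.read_csv(path)
    return MotionTrace(
        df["time_s"].to_numpy(),
        df["position_mm"].to_numpy(),
        df["beam_on"].to_numpy().astype(bool),
        meta=meta or {},
    )
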