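"""In-memory carriers shared by every analysis module.

All rasters use millimetre physical coordinates with the origin at the image
centre; x is the cross-plane (lateral) axis and runs along columns, y is the
in-plane (longitudinal) axis and runs along rows.  This matches the film and
beam coordinate convention used throughout (x lateral, y longitudinal for a
head-first-supine setup).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DoseImage",
    "GrayImage",
    "BeamProfile",
    "SpectrumProfile",
    "MotionTrace",
    "Roi",
    "RoiStats",
]

#: permissible pixel-value interpretations for a :class:`DoseImage`
IMAGE_UNITS = ("dose", "od", "raw")


@dataclass
class DoseImage:
    """2-D raster of dose (or optical-density) values with pixel geometry.

    Parameters
    ----------
    values
        2-D array, ``values[row, col]`` with row = in-plane (y) and
        col = cross-plane (x).
    pixel_spacing_mm
        Isotropic pixel pitch in millimetres; must be positive.
    origin_mm
        Physical (x, y) position of the image centre in millimetres.
    units
        One of ``dose``, ``od`` (optical density) or ``raw``.
    """

    values: np.ndarray
    pixel_spacing_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)
    units: str = "dose"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D raster")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.units not in IMAGE_UNITS:
            raise ValueError(f"units must be one of {IMAGE_UNITS}")
        self.origin_mm = (float(self.origin_mm[0]), float(self.origin_mm[1]))

    # -- geometry -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def x_mm(self) -> np.ndarray:
        """Physical x (cross-plane) coordinate of every column centre."""
        n = self.values.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_spacing_mm + self.origin_mm[0]

    @property
    def y_mm(self) -> np.ndarray:
        """Physical y (in-plane) coordinate of every row centre."""
        n = self.values.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) * self.pixel_spacing_mm + self.origin_mm[1]

    def to_pixel(self, x_mm: np.ndarray, y_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Convert physical mm coordinates to fractional (row, col) indices."""
        ny, nx = self.values.shape
        col = (np.asarray(x_mm, float) - self.origin_mm[0]) / self.pixel_spacing_mm + (nx - 1) / 2.0
        row = (np.asarray(y_mm, float) - self.origin_mm[1]) / self.pixel_spacing_mm + (ny - 1) / 2.0
        return row, col


#: MR phantom images share the raster geometry of films; the alias keeps the
#: intent explicit at call sites.
GrayImage = DoseImage


@dataclass
class BeamProfile:
    """Ordered (position, value) series along one beam axis."""

    positions_cm: np.ndarray
    values: np.ndarray
    axis: str = "cross_plane"  # cross_plane | in_plane

    def __post_init__(self) -> None:
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions_cm.ndim != 1 or self.positions_cm.shape != self.values.shape:
            raise ValueError("positions and values must be matching 1-D arrays")
        if self.positions_cm.size < 8:
            raise ValueError("profile needs at least 8 samples")
        if np.any(np.diff(self.positions_cm) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.axis not in ("cross_plane", "in_plane"):
            raise ValueError("axis must be cross_plane or in_plane")


@dataclass
class SpectrumProfile:
    """Magnitude spectrum around the proton resonance peak."""

    frequency_hz: np.ndarray
    magnitude: np.ndarray
    #: design central frequency of the 0.35 T system (Hz)
    nominal_f0_hz: float = 14_701_760.0

    def __post_init__(self) -> None:
        self.frequency_hz = np.asarray(self.frequency_hz, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if self.frequency_hz.shape != self.magnitude.shape or self.frequency_hz.ndim != 1:
            raise ValueError("frequency and magnitude must be matching 1-D arrays")
        if np.any(np.diff(self.frequency_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if not self.nominal_f0_hz > 0:
            raise ValueError("nominal_f0_hz must be positive")


@dataclass
class MotionTrace:
    """Sampled target motion with the concurrent beam state.

    ``meta`` carries generator ground truth (injected latency, gating
    boundary) when the trace is synthetic.
    """

    time_s: np.ndarray
    position_mm: np.ndarray
    beam_on: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        self.beam_on = np.asarray(self.beam_on, dtype=bool)
        if not (self.time_s.shape == self.position_mm.shape == self.beam_on.shape):
            raise ValueError("time, position and beam state must align")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class Roi:
    """Region of interest in physical millimetres.

    ``shape='rect'`` uses ``size_mm=(width, height)``; ``shape='circle'``
    uses ``size_mm=(diameter,)`` or a scalar diameter.
    """

    center_mm: tuple[float, float]
    size_mm: tuple[float, ...] | float
    shape: str = "rect"

    def __post_init__(self) -> None:
        if self.shape not in ("rect", "circle"):
            raise ValueError("shape must be rect or circle")
        if np.isscalar(self.size_mm):
            self.size_mm = (float(self.size_mm),)
        else:
            self.size_mm = tuple(float(s) for s in self.size_mm)
        if any(s <= 0 for s in self.size_mm):
            raise ValueError("ROI size must be positive")

    def mask(self, image: DoseImage) -> np.ndarray:
        """Boolean pixel mask of the ROI on ``image``'s grid."""
        X, Y = np.meshgrid(image.x_mm, image.y_mm)
        cx, cy = self.center_mm
        if self.shape == "rect":
            w = self.size_mm[0]
            h = self.size_mm[1] if len(self.size_mm) > 1 else w
            m = (np.abs(X - cx) <= w / 2.0) & (np.abs(Y - cy) <= h / 2.0)
        else:
            r = self.size_mm[0] / 2.0
            m = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
        if not m.any():
            raise ValueError("ROI does not overlap the image")
        return m

    def extract(self, image: DoseImage) -> np.ndarray:
        """Pixel values inside the ROI (flat array)."""
        return image.values[self.mask(image)]

    def stats(self, image: DoseImage, ddof: int = 1) -> "RoiStats":
        vals = self.extract(image)
        return RoiStats(
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0,
            min=float(vals.min()),
            max=float(vals.max()),
            roi=self,
            n=int(vals.size),
        )


@dataclass
class RoiStats:
    """Summary statistics over a declared region."""

    mean: float
    sd: float
    min: float
    max: float
    roi: Roi
    n: int

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError("inconsistent ROI statistics")
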