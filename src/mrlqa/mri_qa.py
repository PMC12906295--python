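"""MR-side analyses.

B0 homogeneity as the spectral FWHM in ppm, NEMA-style SNR and uniformity,
ACR-style image-quality metrics (signal ghosting, integral uniformity,
slice thickness and position), and grid-phantom spatial integrity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import center_of_mass, uniform_filter

from .containers import GrayImage, Roi, SpectrumProfile
from .synthetic_data import GridPhantomSpec

__all__ = [
    "HomogeneityResult",
    "DistortionResult",
    "CENTRAL_FREQUENCY_RANGE_HZ",
    "spectral_homogeneity",
    "check_central_frequency",
    "snr",
    "uniformity",
    "percent_signal_ghosting",
    "percent_integral_uniformity",
    "slice_thickness",
    "slice_position",
    "spatial_integrity",
]

#: permissible central-frequency window for the 0.35 T magnet (Hz)
CENTRAL_FREQUENCY_RANGE_HZ = (14_686_760.0, 14_716_760.0)


# ----------------------------------------------------------------------
# B0 homogeneity
# ----------------------------------------------------------------------
@dataclass
class HomogeneityResult:
    fwhm_hz: float
    ppm: float
    cf_used_hz: float
    within_tolerance: bool  # <= 5 ppm

    def __post_init__(self) -> None:
        if abs(self.ppm - self.fwhm_hz / self.cf_used_hz * 1e6) > 1e-9:
            raise ValueError("ppm must equal fwhm_hz / cf * 1e6")


def _half_max_width(x: np.ndarray, y: np.ndarray) -> float:
    """FWHM of a single dominant peak via interpolated half-max crossings."""
    ipk = int(np.argmax(y))
    half = y[ipk] / 2.0
    left = right = None
    i = ipk
    while i > 0:
        if (y[i - 1] - half) * (y[i] - half) <= 0 and y[i - 1] <= half:
            a, b = y[i - 1] - half, y[i] - half
            left = x[i - 1] + (x[i] - x[i - 1]) * a / (a - b) if b != a else x[i - 1]
            break
        i -= 1
    i = ipk
    while i < len(x) - 1:
        if (y[i] - half) * (y[i + 1] - half) <= 0 and y[i + 1] <= half:
            a, b = y[i] - half, y[i + 1] - half
            right = x[i] + (x[i + 1] - x[i]) * a / (a - b) if b != a else x[i + 1]
            break
        i += 1
    if left is None or right is None:
        raise ValueError("peak does not cross half maximum on both sides")
    return float(right - left)


def spectral_homogeneity(spectrum: SpectrumProfile, cf_mode: str = "nominal") -> HomogeneityResult:
    """B0 homogeneity from a resonance spectrum, in ppm.

    The linewidth is the FWHM of the magnitude peak (linear-interpolated
    half-max crossings); ppm = FWHM(Hz) / f0 * 1e6.  ``cf_mode='nominal'``
    divides by the spectrum's nominal central frequency (the convention for
    the worst/best-case reporting), ``'peak'`` by the detected peak
    frequency.  Homogeneity within tolerance means <= 5 ppm.
    """
    if cf_mode not in ("nominal", "peak"):
        raise ValueError("cf_mode must be 'nominal' or 'peak'")
    mag = spectrum.magnitude
    if mag.max() <= 2.0 * np.median(mag):
        raise ValueError("peak magnitude must exceed twice the baseline")
    width = _half_max_width(spectrum.frequency_hz, mag)
    cf = (
        spectrum.nominal_f0_hz
        if cf_mode == "nominal"
        else float(spectrum.frequency_hz[np.argmax(mag)])
    )
    ppm = width / cf * 1e6
    return HomogeneityResult(width, ppm, cf, within_tolerance=ppm <= 5.0)


def check_central_frequency(f0_hz: float) -> bool:
    """True iff f0 lies in the permissible closed range around 14.70176 MHz."""
    lo, hi = CENTRAL_FREQUENCY_RANGE_HZ
    return lo <= f0_hz <= hi


# ----------------------------------------------------------------------
# NEMA SNR / uniformity
# ----------------------------------------------------------------------
def snr(image: GrayImage, signal_roi: Roi, noise_roi: Roi) -> float:
    """NEMA single-image SNR: 0.66 x signal-ROI mean / noise-ROI SD."""
    sig = signal_roi.stats(image)
    noi = noise_roi.stats(image)
    if noi.sd <= 0:
        raise ValueError("noise ROI standard deviation must be positive")
    return 0.66 * sig.mean / noi.sd


def _filtered_roi_extrema(image: GrayImage, roi: Roi, prefilter_mm: float) -> tuple[float, float]:
    """(max, min) of the mean-filtered image restricted to the ROI."""
    size = max(1, int(round(prefilter_mm / image.pixel_spacing_mm)))
    filt = uniform_filter(image.values, size=size, mode="nearest")
    vals = filt[roi.mask(image)]
    return float(vals.max()), float(vals.min())


def uniformity(image: GrayImage, roi: Roi, prefilter_mm: float = 3.0) -> float:
    """NEMA uniformity 100*(1 - (max-min)/(max+min)) over a low-passed ROI.

    A small mean filter (default 3 mm, i.e. 3x3 pixels at 1 mm pitch) is
    applied before taking the extrema, per NEMA practice.
    """
    mx, mn = _filtered_roi_extrema(image, roi, prefilter_mm)
    if mx + mn == 0:
        raise ValueError("max + min signal is zero; uniformity undefined")
    return 100.0 * (1.0 - (mx - mn) / (mx + mn))


# ----------------------------------------------------------------------
# ACR-style metrics
# ----------------------------------------------------------------------
def percent_signal_ghosting(
    image: GrayImage,
    center_roi: Roi,
    edge_rois: Mapping[str, Roi],
) -> float:
    """ACR percent signal ghosting from four background edge ROIs.

    PSG = |(top + bottom) - (left + right)| / (2 x centre mean), using ROI
    means; returned as a fraction (tolerance < 0.025).
    """
    missing = {"top", "bottom", "left", "right"} - set(edge_rois)
    if missing:
        raise ValueError(f"missing edge ROIs: {sorted(missing)}")
    c = center_roi.stats(image).mean
    if c <= 0:
        raise ValueError("centre ROI mean must be positive")
    m = {k: edge_rois[k].stats(image).mean for k in ("top", "bottom", "left", "right")}
    return abs((m["top"] + m["bottom"]) - (m["left"] + m["right"])) / (2.0 * c)


def percent_integral_uniformity(image: GrayImage, roi: Roi, window_mm: float = 10.0) -> float:
    """ACR percent integral uniformity over high/low small-ROI means.

    The large ROI is scanned with a mean filter of ``window_mm`` and PIU is
    the uniformity formula applied to the highest and lowest window means.
    """
    mx, mn = _filtered_roi_extrema(image, roi, window_mm)
    if mx + mn == 0:
        raise ValueError("max + min signal is zero; PIU undefined")
    return 100.0 * (1.0 - (mx - mn) / (mx + mn))


def slice_thickness(top_len_mm: float, bottom_len_mm: float) -> float:
    """ACR ramp-length slice thickness: 0.2 * (top*bottom)/(top+bottom) mm."""
    if top_len_mm <= 0 or bottom_len_mm <= 0:
        raise ValueError("ramp lengths must be positive")
    return 0.2 * (top_len_mm * bottom_len_mm) / (top_len_mm + bottom_len_mm)


def slice_position(bar_diff_mm: float) -> float:
    """ACR slice position error: half the bar-length difference (mm)."""
    return bar_diff_mm / 2.0


# ----------------------------------------------------------------------
# spatial integrity
# ----------------------------------------------------------------------
@dataclass
class DistortionResult:
    deviations_mm: np.ndarray
    mean_mm: float
    max_mm: float
    radius_bins: dict[tuple[float, float], float]  # (r_lo, r_hi) -> mean deviation
    detected_mm: np.ndarray
    nominal_mm: np.ndarray


def spatial_integrity(
    image: GrayImage,
    nominal_grid: GridPhantomSpec,
    dsv_radii_mm: Sequence[float] = (50.0, 100.0, 175.0),
    detection_threshold: float = 0.1,
    min_detected_frac: float = 0.9,
) -> DistortionResult:
    """Marker deviations of a grid-phantom image from its nominal layout.

    Each marker is located by the local centre of mass in a window about
    its nominal position; the deviation is |detected - nominal|.  Summaries
    are reported overall and grouped into radial bins (distance from the
    isocenter) bounded by ``dsv_radii_mm``.
    """
    nominal = nominal_grid.nominal_positions_mm()
    half_win = nominal_grid.marker_spacing_mm / 2.0
    gmax = image.values.max()
    x, y = image.x_mm, image.y_mm
    detected, kept, missing = [], [], []
    for idx, (nx_, ny_) in enumerate(nominal):
        cols = np.nonzero(np.abs(x - nx_) <= half_win)[0]
        rows = np.nonzero(np.abs(y - ny_) <= half_win)[0]
        if cols.size == 0 or rows.size == 0:
            missing.append(idx)
            continue
        sub = image.values[np.ix_(rows, cols)]
        if sub.max() < detection_threshold * gmax:
            missing.append(idx)
            continue
        w = np.clip(sub - 0.05 * sub.max(), 0.0, None)
        r, c = center_of_mass(w)
        detected.append([np.interp(c, np.arange(cols.size), x[cols]),
                         np.interp(r, np.arange(rows.size), y[rows])])
        kept.append(idx)
    if len(kept) < min_detected_frac * len(nominal):
        raise ValueError(
            f"only {len(kept)}/{len(nominal)} markers detected; missing indices {missing}"
        )
    detected = np.asarray(detected)
    nom_kept = nominal[kept]
    dev = np.linalg.norm(detected - nom_kept, axis=1)
    radii = np.linalg.norm(nom_kept, axis=1)
    edges = [0.0, *sorted(dsv_radii_mm)]
    bins: dict[tuple[float, float], float] = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (radii >= lo) & (radii < hi)
        if sel.any():
            bins[(lo, hi)] = float(dev[sel].mean())
    return DistortionResult(
        deviations_mm=dev,
        mean_mm=float(dev.mean()),
        max_mm=float(dev.max()),
        radius_bins=bins,
        detected_mm=detected,
        nominal_mm=nom_kept,
    )
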