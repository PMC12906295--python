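"""1-D/2-D dose-distribution analytics.

FWHM field size, 20-80% penumbra, pointwise flatness and symmetry against
TPS values, field output factors, and the 2-D gamma index.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .containers import BeamProfile, DoseImage

__all__ = [
    "fwhm",
    "field_size_difference",
    "penumbra",
    "PenumbraResult",
    "flatness_symmetry",
    "PointComparison",
    "PairComparison",
    "fof_table",
    "fof_difference",
    "FOFEntry",
    "gamma_2d",
    "GammaResult",
    "smooth_profile",
]


# ----------------------------------------------------------------------
# crossing helpers
# ----------------------------------------------------------------------
def _all_crossings(x: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """Positions where the piecewise-linear series crosses ``level``."""
    d = y - level
    out = []
    for i in range(len(x) - 1):
        a, b = d[i], d[i + 1]
        if a == 0.0:
            out.append(x[i])
        elif a * b < 0:
            out.append(x[i] + (x[i + 1] - x[i]) * a / (a - b))
    if len(x) and d[-1] == 0.0:
        out.append(x[-1])
    return np.asarray(out)


def _crossing_from(x, y, level, start, direction):
    """First linear-interpolated crossing of ``level`` walking from ``start``.

    ``direction`` is -1 (towards smaller indices) or +1.
    """
    i = start
    while 0 <= i + direction < len(x):
        j = i + direction
        a, b = y[i] - level, y[j] - level
        if a == 0.0:
            return x[i]
        if a * b < 0:
            return x[i] + (x[j] - x[i]) * a / (a - b)
        i = j
    return None


def smooth_profile(profile: BeamProfile, window: int = 3) -> BeamProfile:
    """Optional moving-average smoothing (off by default in all analyses)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    k = np.ones(window) / window
    pad = window // 2
    padded = np.pad(profile.values, pad, mode="edge")
    return BeamProfile(profile.positions_cm, np.convolve(padded, k, mode="valid"), profile.axis)


# ----------------------------------------------------------------------
# FWHM / field size
# ----------------------------------------------------------------------
def fwhm(profile: BeamProfile) -> float:
    """Full width at half maximum of a single-lobe profile, in cm.

    Half-maximum crossings are located by linear interpolation; the profile
    must cross half-max exactly twice (multi-lobe data are rejected).
    """
    x, y = profile.positions_cm, profile.values
    m = float(y.max())
    if m <= 0:
        raise ValueError("profile maximum must be positive")
    crossings = _all_crossings(x, y, m / 2.0)
    if len(crossings) != 2:
        raise ValueError(
            f"profile crosses half-maximum {len(crossings)} times; expected 2 (multi-lobe?)"
        )
    return float(crossings[1] - crossings[0])


def field_size_difference(measured_cm: float, tps_cm: float) -> float:
    """Measured minus TPS field size (cm)."""
    if measured_cm <= 0 or tps_cm <= 0:
        raise ValueError("field sizes must be positive")
    return measured_cm - tps_cm


# ----------------------------------------------------------------------
# penumbra
# ----------------------------------------------------------------------
@dataclass
class PenumbraResult:
    left_mm: float
    right_mm: float
    mean_mm: float
    normalized: bool

    def __post_init__(self) -> None:
        if abs(self.mean_mm - (self.left_mm + self.right_mm) / 2.0) > 1e-9:
            raise ValueError("mean must equal (left+right)/2")


def penumbra(profile: BeamProfile, normalize: bool = True) -> PenumbraResult:
    """Distance between the 20% and 80% isodose levels at each field edge.

    With ``normalize=True`` the profile is rescaled to 100 at its maximum
    before thresholding, so the 20/80 levels are relative to the profile
    maximum (the convention for the larger fields).  With
    ``normalize=False`` the values are taken as given, i.e. already on a
    percent scale, and the absolute 20 and 80 levels are used.
    """
    x = profile.positions_cm
    y = profile.values.astype(float)
    if y.max() <= 0:
        raise ValueError("profile maximum must be positive")
    if normalize:
        y = y / y.max() * 100.0
    lo, hi = 20.0, 80.0
    ipk = int(np.argmax(y))
    left20 = _crossing_from(x, y, lo, ipk, -1)
    left80 = _crossing_from(x, y, hi, ipk, -1)
    right80 = _crossing_from(x, y, hi, ipk, +1)
    right20 = _crossing_from(x, y, lo, ipk, +1)
    if None in (left20, left80, right20, right80):
        raise ValueError("profile does not cross both the 20% and 80% levels on both edges")
    left = (left80 - left20) * 10.0
    right = (right20 - right80) * 10.0
    return PenumbraResult(left, right, (left + right) / 2.0, normalize)


# ----------------------------------------------------------------------
# flatness / symmetry
# ----------------------------------------------------------------------
@dataclass
class PointComparison:
    """One off-axis point: measured vs TPS, with the pointwise flatness F."""

    oap_cm: float
    tps_pct: float
    measured_pct: float
    flatness_diff_pct: float  # M - TPS

    def __post_init__(self) -> None:
        if abs(self.flatness_diff_pct - (self.measured_pct - self.tps_pct)) > 1e-9:
            raise ValueError("flatness_diff must equal measured - tps")


@dataclass
class PairComparison:
    """A +-OAP pair with its symmetry S = M(-OAP) - M(+OAP)."""

    oap_cm: float  # positive magnitude
    minus: PointComparison
    plus: PointComparison
    symmetry_pct: float
    tolerance_pct: float = 2.0

    @property
    def flatness_within(self) -> bool:
        return (
            abs(self.minus.flatness_diff_pct) <= self.tolerance_pct
            and abs(self.plus.flatness_diff_pct) <= self.tolerance_pct
        )

    @property
    def symmetry_within(self) -> bool:
        return abs(self.symmetry_pct) <= self.tolerance_pct


def flatness_symmetry(
    points: Sequence[tuple[float, float, float]],
    tolerance_pct: float = 2.0,
) -> list[PairComparison]:
    """Complete flatness/symmetry comparisons for +-OAP point pairs.

    ``points`` is a sequence of ``(oap_cm, tps_pct, measured_pct)`` covering
    both signs of each off-axis position.  Per point F = M - TPS; per pair
    S = M(-OAP) - M(+OAP); verdicts compare |F| and |S| with the tolerance
    (2% by default).
    """
    by_oap: dict[float, dict[int, tuple[float, float]]] = {}
    for oap, tps, meas in points:
        mag = round(abs(float(oap)), 9)
        if mag == 0:
            raise ValueError("off-axis points must be nonzero to form +- pairs")
        sign = 1 if oap > 0 else -1
        slot = by_oap.setdefault(mag, {})
        if sign in slot:
            raise ValueError(f"duplicate off-axis point {oap}")
        slot[sign] = (float(tps), float(meas))
    pairs = []
    for mag in sorted(by_oap):
        slot = by_oap[mag]
        if set(slot) != {-1, 1}:
            raise ValueError(f"unpaired off-axis point at +-{mag} cm")
        tps_m, meas_m = slot[-1]
        tps_p, meas_p = slot[1]
        pairs.append(
            PairComparison(
                oap_cm=mag,
                minus=PointComparison(-mag, tps_m, meas_m, meas_m - tps_m),
                plus=PointComparison(mag, tps_p, meas_p, meas_p - tps_p),
                symmetry_pct=meas_m - meas_p,
                tolerance_pct=tolerance_pct,
            )
        )
    return pairs


# ----------------------------------------------------------------------
# field output factors
# ----------------------------------------------------------------------
@dataclass
class FOFEntry:
    field_label: str
    mean_reading: float
    fof: float
    tps_fof: float | None = None
    diff_pct: float | None = None


def fof_difference(measured_fof: float, tps_fof: float) -> float:
    """Percent difference of output factors, TPS in the denominator, 1 dp."""
    if tps_fof == 0:
        raise ValueError("TPS output factor must be nonzero")
    return round(100.0 * (measured_fof - tps_fof) / tps_fof, 1)


def fof_table(
    readings_by_field: Mapping[str, Sequence[float]],
    reference_label: str,
    tps_fof: Mapping[str, float] | None = None,
) -> list[FOFEntry]:
    """Field output factors from replicate detector readings.

    Each field's replicates are averaged and divided by the reference
    field's average; the reference FOF is identically 1.  When TPS factors
    are supplied the percent difference (TPS denominator, 1 dp) is filled
    in.
    """
    if reference_label not in readings_by_field:
        raise ValueError(f"reference field {reference_label!r} missing from readings")
    means = {}
    for label, reads in readings_by_field.items():
        arr = np.asarray(list(reads), dtype=float)
        if arr.size == 0 or np.any(arr <= 0):
            raise ValueError(f"readings for {label!r} must be positive and nonempty")
        means[label] = float(arr.mean())
    ref = means[reference_label]
    entries = []
    for label, mean in means.items():
        fof = mean / ref
        tps = None if tps_fof is None else tps_fof.get(label)
        diff = None if tps is None else fof_difference(fof, tps)
        entries.append(FOFEntry(label, mean, fof, tps, diff))
    return entries


# ----------------------------------------------------------------------
# 2-D gamma index
# ----------------------------------------------------------------------
@dataclass
class GammaResult:
    gamma_map: np.ndarray
    pass_rate_pct: float
    dose_crit_pct: float
    dta_mm: float
    normalization: str
    n_evaluated: int


def gamma_2d(
    ref: DoseImage,
    ev: DoseImage,
    dose_crit_pct: float = 3.0,
    dta_mm: float = 3.0,
    normalization: str = "global",
    search_factor: float = 3.0,
    resample_step_mm: float | None = None,
) -> GammaResult:
    """2-D gamma index of an evaluated dose distribution against a reference.

    For every reference point, gamma is the minimum over evaluated points of
    ``sqrt((dD/D_crit)^2 + (dr/DTA)^2)``; the evaluated distribution is
    bilinearly resampled to a grid no coarser than ``0.1 * DTA`` and the
    search is limited to a radius of ``search_factor * DTA``.  Global
    normalisation scales the dose criterion by the reference maximum; local
    normalisation by each reference point's own dose.  Points with gamma
    <= 1 pass.
    """
    if normalization not in ("global", "local"):
        raise ValueError("normalization must be 'global' or 'local'")
    if dose_crit_pct <= 0 or dta_mm <= 0:
        raise ValueError("criteria must be positive")
    rx, ry = ref.x_mm, ref.y_mm
    ex, ey = ev.x_mm, ev.y_mm
    if rx.max() < ex.min() or ex.max() < rx.min() or ry.max() < ey.min() or ey.max() < ry.min():
        raise ValueError("reference and evaluated extents are disjoint")

    if resample_step_mm is not None:
        fx = np.arange(ex.min(), ex.max() + resample_step_mm / 2, resample_step_mm)
        fy = np.arange(ey.min(), ey.max() + resample_step_mm / 2, resample_step_mm)
    else:
        # subdivide the native grid so eval nodes stay exactly on the fine grid
        sub = max(1, int(np.ceil(ev.pixel_spacing_mm / (0.1 * dta_mm))))
        fx = np.linspace(ex.min(), ex.max(), (ex.size - 1) * sub + 1)
        fy = np.linspace(ey.min(), ey.max(), (ey.size - 1) * sub + 1)
    interp = RegularGridInterpolator((ey, ex), ev.values, method="linear", bounds_error=False)
    FX, FY = np.meshgrid(fx, fy)
    fine = interp(np.column_stack([FY.ravel(), FX.ravel()])).reshape(FY.shape)

    radius = search_factor * dta_mm
    gmap = np.full(ref.values.shape, np.nan)
    global_crit = dose_crit_pct / 100.0 * float(ref.values.max())
    for i in range(ref.values.shape[0]):
        y0 = ry[i]
        jy = np.nonzero(np.abs(fy - y0) <= radius)[0]
        if jy.size == 0:
            continue
        dy2 = (fy[jy] - y0) ** 2
        for j in range(ref.values.shape[1]):
            x0 = rx[j]
            jx = np.nonzero(np.abs(fx - x0) <= radius)[0]
            if jx.size == 0:
                continue
            d0 = ref.values[i, j]
            crit = global_crit if normalization == "global" else dose_crit_pct / 100.0 * d0
            if crit <= 0:
                continue
            dx2 = (fx[jx] - x0) ** 2
            r2 = (dy2[:, None] + dx2[None, :]) / dta_mm**2
            dd2 = ((fine[np.ix_(jy, jx)] - d0) / crit) ** 2
            gmap[i, j] = np.sqrt(np.nanmin(dd2 + r2))
    evaluated = np.isfinite(gmap)
    n_eval = int(evaluated.sum())
    if n_eval == 0:
        raise ValueError("no reference points could be evaluated")
    pass_rate = 100.0 * float((gmap[evaluated] <= 1.0 + 1e-9).sum()) / n_eval
    return GammaResult(gmap, pass_rate, dose_crit_pct, dta_mm, normalization, n_eval)
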