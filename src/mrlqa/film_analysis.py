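"""Film-image analyses.

Calibration, starshot isocentricity (minimum tangent circle), picket-fence
MLC position accuracy, closed-MLC transmission / interleaf leakage, and
small-field size measurement.

The starshot radiation isocenter is defined as the centre of the minimum
circle tangent to all spoke centre-lines.  Each spoke is reduced to a line
by sampling the film on two concentric circles about the intensity-weighted
centre, locating the strip crossings, and refining with orthogonal (total
least squares) regression; the centre is then the Chebyshev centre of the
line set — the point minimising the maximum perpendicular distance to all
lines — solved as a linear minimax program.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.optimize import linprog, minimize

from .containers import BeamProfile, DoseImage
from .profile_analysis import fwhm

__all__ = [
    "SpokeLine",
    "StarshotResult",
    "PicketFenceResult",
    "LeakageResult",
    "FilmFieldSize",
    "calibrate_film",
    "analyze_starshot",
    "chebyshev_center",
    "analyze_picketfence",
    "leaf_shift_stats",
    "analyze_leakage",
    "measure_field_size_film",
]


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------
def calibrate_film(image: DoseImage, curve: Callable[[np.ndarray], np.ndarray]) -> DoseImage:
    """Apply a strictly monotone optical-density -> dose calibration curve.

    ``curve`` maps OD to dose pixelwise; spacing and origin are preserved.
    If the curve exposes a ``domain`` attribute, optical densities outside
    it are rejected with a range report.  Monotonicity is checked over the
    image's OD range.
    """
    if image.units != "od":
        raise ValueError("calibrate_film expects an image in optical-density units")
    od = image.values
    lo, hi = float(od.min()), float(od.max())
    domain = getattr(curve, "domain", None)
    if domain is not None and (lo < domain[0] or hi > domain[1]):
        raise ValueError(
            f"optical densities [{lo:.4g}, {hi:.4g}] fall outside the "
            f"calibration domain [{domain[0]:.4g}, {domain[1]:.4g}]"
        )
    if hi > lo:
        grid = np.linspace(lo, hi, 513)
        if np.any(np.diff(np.asarray(curve(grid), dtype=float)) <= 0):
            raise ValueError("calibration curve is not strictly monotone over the OD range")
    dose = np.asarray(curve(od), dtype=float)
    return DoseImage(dose, image.pixel_spacing_mm, image.origin_mm, units="dose")


# ----------------------------------------------------------------------
# starshot
# ----------------------------------------------------------------------
@dataclass
class SpokeLine:
    """A spoke centre-line: unit normal (nx, ny) and offset d, n.p = d."""

    nx: float
    ny: float
    d: float

    @property
    def angle_deg(self) -> float:
        """Direction of the line (degrees, modulo 180)."""
        return float(np.mod(np.rad2deg(np.arctan2(-self.nx, self.ny)), 180.0))

    def distance(self, point: Sequence[float]) -> float:
        return abs(self.nx * point[0] + self.ny * point[1] - self.d)


@dataclass
class StarshotResult:
    center_mm: tuple[float, float]
    radius_mm: float
    spoke_lines: list[tuple[float, float]]  # (angle_deg, signed offset from center)
    n_spokes: int


def chebyshev_center(lines: Sequence[SpokeLine]) -> tuple[tuple[float, float], float]:
    """Point minimising the maximum perpendicular distance to the lines.

    Solved as the linear program min t s.t. |n_i . c - d_i| <= t.  Among
    centres attaining the optimum (degenerate instances), the least-squares
    centre is preferred.
    """
    if len(lines) < 3:
        raise ValueError("at least 3 lines are required")
    N = np.array([[ln.nx, ln.ny] for ln in lines])
    d = np.array([ln.d for ln in lines])
    A = np.vstack([np.column_stack([N, -np.ones(len(d))]),
                   np.column_stack([-N, -np.ones(len(d))])])
    b = np.concatenate([d, -d])
    res = linprog(c=[0.0, 0.0, 1.0], A_ub=A, b_ub=b, bounds=[(None, None)] * 3, method="highs")
    if not res.success:
        raise RuntimeError(f"minimax LP failed: {res.message}")
    cx, cy, t = res.x
    # tie-break: least-squares centre within the optimal slab
    try:
        ls = minimize(
            lambda p: float(np.sum((N @ p - d) ** 2)),
            x0=[cx, cy],
            constraints=[{
                "type": "ineq",
                "fun": lambda p: (t + 1e-9) - np.abs(N @ p - d),
            }],
            method="SLSQP",
        )
        if ls.success and np.max(np.abs(N @ ls.x - d)) <= t + 1e-6:
            cx, cy = ls.x
            t = float(np.max(np.abs(N @ ls.x - d)))
    except Exception:  # pragma: no cover - polish is best-effort
        pass
    return (float(cx), float(cy)), float(t)


def _circle_peak_points(image: DoseImage, center: np.ndarray, radius: float, n_theta: int = 4096):
    """Strip-crossing points on a sampling circle, with sub-sample centroids."""
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    xs = center[0] + radius * np.cos(theta)
    ys = center[1] + radius * np.sin(theta)
    row, col = image.to_pixel(xs, ys)
    vals = map_coordinates(image.values, [row, col], order=1, mode="nearest")
    thr = 0.5 * vals.max()
    mask = vals > thr
    if not mask.any() or mask.all():
        return np.empty((0, 2)), np.empty(0)
    # rotate so the series starts outside a peak, then label contiguous runs
    start = int(np.argmin(mask))
    mask_r = np.roll(mask, -start)
    vals_r = np.roll(vals, -start)
    theta_r = theta[(np.arange(n_theta) + start) % n_theta]
    points, angles = [], []
    i = 0
    while i < n_theta:
        if mask_r[i]:
            j = i
            while j < n_theta and mask_r[j]:
                j += 1
            w = vals_r[i:j] - thr
            th_seg = np.unwrap(theta_r[i:j])
            th_c = float(np.sum(w * th_seg) / np.sum(w))
            points.append([center[0] + radius * np.cos(th_c), center[1] + radius * np.sin(th_c)])
            angles.append(np.mod(th_c, 2 * np.pi))
            i = j
        else:
            i += 1
    return np.asarray(points), np.asarray(angles)


def _tls_line(points: np.ndarray) -> SpokeLine:
    """Orthogonal-regression line through >= 2 points."""
    m = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - m)
    direction = vt[0]
    n = np.array([-direction[1], direction[0]])
    if n[1] < 0 or (n[1] == 0 and n[0] < 0):  # canonical normal orientation
        n = -n
    return SpokeLine(float(n[0]), float(n[1]), float(n @ m))


def analyze_starshot(image: DoseImage, n_spokes: int) -> StarshotResult:
    """Locate the radiation isocenter of a starshot film.

    Spokes are detected on two concentric sampling circles about the
    intensity-weighted centre, paired across circles, grouped by direction
    (modulo 180 deg) and refined by orthogonal regression; the result is the
    Chebyshev centre of the fitted lines and the radius of the minimum
    tangent circle.
    """
    if n_spokes < 3:
        raise ValueError("a starshot needs at least 3 spokes")
    vals = np.clip(image.values, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("image has no signal")
    X, Y = np.meshgrid(image.x_mm, image.y_mm)
    seed = np.array([float((vals * X).sum() / total), float((vals * Y).sum() / total)])
    border = min(
        seed[0] - image.x_mm.min(), image.x_mm.max() - seed[0],
        seed[1] - image.y_mm.min(), image.y_mm.max() - seed[1],
    )
    radii = (0.45 * border, 0.8 * border)
    pts1, ang1 = _circle_peak_points(image, seed, radii[0])
    pts2, ang2 = _circle_peak_points(image, seed, radii[1])
    if len(pts1) != 2 * n_spokes or len(pts2) != 2 * n_spokes:
        raise ValueError(
            f"detected {len(pts1)}/{len(pts2)} strip crossings on the sampling circles, "
            f"expected {2 * n_spokes}; crossing angles (deg): "
            f"{np.round(np.rad2deg(ang1), 1).tolist()}"
        )
    # pair crossings across circles by angular proximity -> one ray per side
    used = np.zeros(len(pts2), dtype=bool)
    rays = []
    for p1, a1 in zip(pts1, ang1):
        dist = np.abs(np.angle(np.exp(1j * (ang2 - a1))))
        dist[used] = np.inf
        k = int(np.argmin(dist))
        used[k] = True
        rays.append((p1, pts2[k]))
    # group the 2n rays into n spokes by direction modulo 180 degrees
    dirs = np.array([
        np.mod(np.rad2deg(np.arctan2(p2[1] - p1[1], p2[0] - p1[0])), 180.0) for p1, p2 in rays
    ])
    order = np.argsort(dirs)
    gaps = np.diff(np.concatenate([dirs[order], [dirs[order[0]] + 180.0]]))
    # split at the n largest circular gaps
    cut = np.sort(np.argsort(gaps)[-n_spokes:])
    groups, start = [], 0
    for c in cut:
        groups.append(order[start : c + 1])
        start = c + 1
    if start < len(order):  # wrap the tail onto the first group
        groups[0] = np.concatenate([order[start:], groups[0]])
    groups = [g for g in groups if len(g)]
    if len(groups) != n_spokes or any(len(g) != 2 for g in groups):
        raise ValueError(
            f"could not group strip crossings into {n_spokes} spokes; "
            f"ray directions (deg): {np.round(dirs, 1).tolist()}"
        )
    lines = []
    for g in groups:
        pts = np.vstack([np.vstack(rays[i]) for i in g])
        lines.append(_tls_line(pts))
    center, radius = chebyshev_center(lines)
    spoke_lines = [
        (ln.angle_deg, float(ln.d - (ln.nx * center[0] + ln.ny * center[1]))) for ln in lines
    ]
    return StarshotResult(center_mm=center, radius_mm=radius,
                          spoke_lines=spoke_lines, n_spokes=n_spokes)


# ----------------------------------------------------------------------
# picket fence
# ----------------------------------------------------------------------
@dataclass
class PicketFenceResult:
    detected_positions_cm: list[float]
    shifts_mm: list[float]
    mean_shift_mm: float
    sd_shift_mm: float


def leaf_shift_stats(shifts_mm: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation of leaf shifts."""
    arr = np.asarray(list(shifts_mm), dtype=float)
    if arr.size < 2:
        raise ValueError("at least two shifts are required")
    return float(arr.mean()), float(arr.std(ddof=1))


def _parabolic_peak(x: np.ndarray, y: np.ndarray, i: int) -> float:
    """Sub-pixel peak via 3-point parabolic interpolation around index i."""
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(x[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(x[i] + np.clip(delta, -1, 1) * (x[i + 1] - x[i]))


def analyze_picketfence(
    image: DoseImage,
    nominal_positions_cm: Sequence[float],
    search_window_mm: float = 15.0,
) -> PicketFenceResult:
    """Measure picket positions along the cross-plane axis of a strip film.

    The film is projected onto the cross-plane axis (mean over rows); each
    picket position is the parabolic-interpolated peak of the projection
    within a window about its nominal position, and the shift is detected
    minus nominal.  Mean and sample SD follow the leaf-shift convention.
    """
    nominal = np.asarray(list(nominal_positions_cm), dtype=float)
    proj = image.values.mean(axis=0)
    x = image.x_mm
    gmax = proj.max()
    detected = []
    for nom_cm in nominal:
        nom = nom_cm * 10.0
        win = np.nonzero(np.abs(x - nom) <= search_window_mm)[0]
        if win.size == 0 or proj[win].max() < 0.2 * gmax:
            raise ValueError(f"no strip detected near the nominal position {nom_cm} cm")
        i = win[int(np.argmax(proj[win]))]
        detected.append(_parabolic_peak(x, proj, i))
    detected = np.asarray(detected)
    shifts = detected - nominal * 10.0
    if len(shifts) >= 2:
        mean, sd = leaf_shift_stats(shifts)
    else:
        mean, sd = float(shifts.mean()), float("nan")
    return PicketFenceResult(
        detected_positions_cm=(detected / 10.0).tolist(),
        shifts_mm=shifts.tolist(),
        mean_shift_mm=mean,
        sd_shift_mm=sd,
    )


# ----------------------------------------------------------------------
# MLC leakage
# ----------------------------------------------------------------------
@dataclass
class LeakageResult:
    avg_leakage_pct: float
    max_leakage_pct: float
    leakage_mu: float
    reference_mu: float
    max_roi_center_mm: tuple[float, float]


def _window_means(sub: np.ndarray, wy: int, wx: int) -> np.ndarray:
    """Means of all fully-contained wy-by-wx windows (integral image)."""
    S = np.zeros((sub.shape[0] + 1, sub.shape[1] + 1))
    S[1:, 1:] = np.cumsum(np.cumsum(sub, axis=0), axis=1)
    sums = S[wy:, wx:] - S[:-wy, wx:] - S[wy:, :-wx] + S[:-wy, :-wx]
    return sums / (wy * wx)


def analyze_leakage(
    leak: DoseImage,
    ref: DoseImage,
    leak_mu: float,
    ref_mu: float,
    roi_mm: tuple[float, float] = (300.0, 300.0),
    max_window_mm: tuple[float, float] = (10.0, 10.0),
    cax_roi_mm: float = 10.0,
) -> LeakageResult:
    """Average and maximum MLC leakage, normalised per MU to the reference.

    Average leakage is the mean dose in the (default 300 x 300 mm) region of
    interest; maximum leakage is the largest mean over sliding (default
    10 x 10 mm) windows fully contained in that region.  Both are divided by
    the reference field's central-axis dose after per-MU normalisation:

        % = 100 * (dose / leak_MU) / (ref_CAX_dose / ref_MU)
    """
    if leak.units != "dose" or ref.units != "dose":
        raise ValueError("both images must be in dose units")
    if leak_mu <= 0 or ref_mu <= 0:
        raise ValueError("monitor units must be positive")
    # ROI centred on the image origin
    half_w, half_h = roi_mm[0] / 2.0, roi_mm[1] / 2.0
    x, y = leak.x_mm, leak.y_mm
    cols = np.nonzero(np.abs(x) <= half_w)[0]
    rows = np.nonzero(np.abs(y) <= half_h)[0]
    if (
        cols.size == 0 or rows.size == 0
        or x.min() > -half_w + leak.pixel_spacing_mm or x.max() < half_w - leak.pixel_spacing_mm
        or y.min() > -half_h + leak.pixel_spacing_mm or y.max() < half_h - leak.pixel_spacing_mm
    ):
        raise ValueError("region of interest exceeds the leakage image bounds")
    sub = leak.values[np.ix_(rows, cols)]
    avg_dose = float(sub.mean())

    # reference central-axis dose from a small window at the origin
    rx, ry_ = ref.x_mm, ref.y_mm
    rcols = np.nonzero(np.abs(rx) <= cax_roi_mm / 2.0)[0]
    rrows = np.nonzero(np.abs(ry_) <= cax_roi_mm / 2.0)[0]
    ref_cax = float(ref.values[np.ix_(rrows, rcols)].mean())
    if ref_cax <= 0:
        raise ValueError("reference central-axis dose must be positive")

    wx = max(1, int(round(max_window_mm[0] / leak.pixel_spacing_mm)))
    wy = max(1, int(round(max_window_mm[1] / leak.pixel_spacing_mm)))
    if wy > sub.shape[0] or wx > sub.shape[1]:
        raise ValueError("sliding window larger than the region of interest")
    means = _window_means(sub, wy, wx)
    k = np.unravel_index(int(np.argmax(means)), means.shape)
    max_dose = float(means[k])
    cy = float(y[rows[0] + k[0]] + (wy - 1) / 2.0 * leak.pixel_spacing_mm)
    cx = float(x[cols[0] + k[1]] + (wx - 1) / 2.0 * leak.pixel_spacing_mm)

    norm = (ref_cax / ref_mu)
    return LeakageResult(
        avg_leakage_pct=100.0 * (avg_dose / leak_mu) / norm,
        max_leakage_pct=100.0 * (max_dose / leak_mu) / norm,
        leakage_mu=float(leak_mu),
        reference_mu=float(ref_mu),
        max_roi_center_mm=(cx, cy),
    )


# ----------------------------------------------------------------------
# small-field size from film
# ----------------------------------------------------------------------
@dataclass
class FilmFieldSize:
    cross_plane_cm: float
    in_plane_cm: float

    def __post_init__(self) -> None:
        if self.cross_plane_cm <= 0 or self.in_plane_cm <= 0:
            raise ValueError("field sizes must be positive")


def measure_field_size_film(image: DoseImage) -> FilmFieldSize:
    """FWHM field size of a single connected field on film.

    Central cross-plane and in-plane profiles are extracted through the
    field's intensity-weighted centroid (bilinear interpolation) and their
    FWHMs define the two field dimensions.
    """
    vals = np.clip(image.values, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("image has no region above half maximum")
    X, Y = np.meshgrid(image.x_mm, image.y_mm)
    cx = float((vals * X).sum() / total)
    cy = float((vals * Y).sum() / total)
    row, _ = image.to_pixel(np.zeros(1), np.array([cy]))
    xs = image.x_mm
    prof_x = map_coordinates(image.values, [np.full_like(xs, row[0]), np.arange(xs.size)], order=1)
    _, col = image.to_pixel(np.array([cx]), np.zeros(1))
    ys = image.y_mm
    prof_y = map_coordinates(image.values, [np.arange(ys.size), np.full_like(ys, col[0])], order=1)
    w_x = fwhm(BeamProfile(xs / 10.0, prof_x, axis="cross_plane"))
    w_y = fwhm(BeamProfile(ys / 10.0, prof_y, axis="in_plane"))
    return FilmFieldSize(cross_plane_cm=w_x, in_plane_cm=w_y)
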