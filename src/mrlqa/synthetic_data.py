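"""Synthetic MR-Linac acceptance-test data with known ground truth.

Every downstream analysis in this package can be exercised without hardware:
this module emulates starshot and picket-fence films, closed-MLC leakage
maps, FFF-shaped beam profiles, resonance spectra, uniform-sphere and grid
phantom images, and sinusoidal target-motion traces with injected
beam-control latency.

Design notes
------------
* Field edges are logistic sigmoids, chosen for their closed-form 20-80%
  penumbra width ``2 s ln 4`` which gives analytic oracles for the profile
  analyses.
* The unflattened (FFF) dome is a shallow quadratic cap on the plateau.
* Film response is generated directly in dose units by default; an optional
  optical-density layer through a monotone rational calibration curve
  exercises film calibration.
* Seeds are explicit arguments everywhere; no global random state is used.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .containers import BeamProfile, DoseImage, GrayImage, MotionTrace, SpectrumProfile

__all__ = [
    "StarshotSpec",
    "ProfileSpec",
    "SpectrumSpec",
    "MotionSpec",
    "GridPhantomSpec",
    "GridPhantomImage",
    "RationalCalibration",
    "gen_starshot_film",
    "gen_picketfence_film",
    "gen_field_profile",
    "gen_spectrum",
    "gen_uniform_phantom_image",
    "gen_grid_phantom_image",
    "gen_motion_trace",
    "gen_leakage_film",
    "gen_field_film",
]


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------
@dataclass
class StarshotSpec:
    """Geometry of a synthetic starshot film.

    Spokes are infinite strips; ``spoke_offsets_mm`` displaces each strip
    centre-line perpendicularly from ``center_mm`` (signed along the strip
    normal), so offsets all equal to ``r`` build lines tangent to a circle
    of radius ``r`` — the construction used as an analytic oracle for the
    minimum-tangent-circle analysis.
    """

    center_mm: tuple[float, float] = (0.0, 0.0)
    spoke_angles_deg: Sequence[float] = (0.0, 72.0, 144.0, 216.0, 288.0)
    spoke_width_mm: float = 10.0
    spoke_offsets_mm: Sequence[float] | None = None
    image_size_px: tuple[int, int] = (240, 240)
    pixel_spacing_mm: float = 0.5
    noise_sd: float = 0.0
    edge_mm: float = 0.4  # softness of the strip edge (film blur surrogate)

    def __post_init__(self) -> None:
        if self.spoke_offsets_mm is None:
            self.spoke_offsets_mm = tuple(0.0 for _ in self.spoke_angles_deg)
        if len(self.spoke_offsets_mm) != len(self.spoke_angles_deg):
            raise ValueError("one offset per spoke angle required")
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if not self.spoke_width_mm > 0:
            raise ValueError("spoke_width_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        ang = np.sort(np.mod(self.spoke_angles_deg, 180.0))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 180.0]]))
        if np.any(gaps < 1e-6):
            raise ValueError("spoke angles must be distinct modulo 180 degrees")


@dataclass
class ProfileSpec:
    """Parameters of a synthetic FFF field profile."""

    nominal_width_cm: float = 9.96
    edge_scale_mm: float = 2.0
    fff_peak_fraction: float = 0.05
    sampling_step_mm: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.nominal_width_cm <= 0 or self.edge_scale_mm <= 0:
            raise ValueError("width and edge scale must be positive")
        if not 0 <= self.fff_peak_fraction <= 1:
            raise ValueError("fff_peak_fraction must lie in [0, 1]")
        if self.sampling_step_mm <= 0:
            raise ValueError("sampling_step_mm must be positive")
        if self.sampling_step_mm > self.edge_scale_mm:
            raise ValueError("sampling step must resolve the edges (step <= edge scale)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SpectrumSpec:
    """Parameters of a synthetic resonance peak."""

    center_frequency_hz: float = 14_701_760.0
    fwhm_hz: float = 50.0
    line_shape: str = "gaussian"  # gaussian | lorentzian
    sampling_step_hz: float = 1.0
    noise_sd: float = 0.0
    span_fwhm: float = 8.0  # half-span of the frequency axis in FWHM units

    def __post_init__(self) -> None:
        if self.center_frequency_hz <= 0 or self.fwhm_hz <= 0:
            raise ValueError("frequency parameters must be positive")
        if self.line_shape not in ("gaussian", "lorentzian"):
            raise ValueError("line_shape must be gaussian or lorentzian")
        if self.sampling_step_hz <= 0 or self.sampling_step_hz > self.fwhm_hz / 10.0:
            raise ValueError("sampling_step_hz must be positive and <= fwhm/10")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class MotionSpec:
    """Sinusoidal target motion with a gated beam.

    Defaults reproduce the gating study conditions: 12 mm amplitude, 4 s
    period, a 3 mm gating boundary, cine imaging at 4 frames per second.
    """

    amplitude_mm: float = 12.0
    period_s: float = 4.0
    frame_rate_fps: float = 4.0
    gating_boundary_mm: float = 3.0
    injected_latency_s: float = 0.0
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if min(self.amplitude_mm, self.period_s, self.frame_rate_fps) <= 0:
            raise ValueError("amplitude, period and frame rate must be positive")
        if self.injected_latency_s < 0:
            raise ValueError("injected_latency_s must be non-negative")
        if self.duration_s < 2 * self.period_s:
            raise ValueError("duration must cover at least two motion periods")


@dataclass
class GridPhantomSpec:
    """Regular marker grid with a controllable distortion field.

    ``distortion_field(xy) -> dxy`` maps an (N, 2) array of nominal marker
    positions (mm) to an (N, 2) array of displacements (mm); ``None`` means
    the identity (no distortion).
    """

    marker_spacing_mm: float = 20.0
    extent_mm: tuple[float, float] = (160.0, 160.0)
    distortion_field: Callable[[np.ndarray], np.ndarray] | None = None
    pixel_spacing_mm: float = 1.0
    marker_sigma_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.marker_spacing_mm <= 0 or self.pixel_spacing_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.marker_spacing_mm <= 4 * self.pixel_spacing_mm:
            raise ValueError("marker spacing must exceed 4 pixels")

    def nominal_positions_mm(self) -> np.ndarray:
        """(N, 2) nominal marker centres on a grid centred at the origin."""
        hx, hy = self.extent_mm[0] / 2.0, self.extent_mm[1] / 2.0
        xs = np.arange(-hx, hx + 1e-9, self.marker_spacing_mm)
        ys = np.arange(-hy, hy + 1e-9, self.marker_spacing_mm)
        X, Y = np.meshgrid(xs, ys)
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass
class GridPhantomImage:
    """Grid-phantom raster plus its ground truth."""

    image: GrayImage
    nominal_mm: np.ndarray
    true_mm: np.ndarray


# ----------------------------------------------------------------------
# film calibration curve
# ----------------------------------------------------------------------
class RationalCalibration:
    """Monotone rational optical-density -> dose calibration.

    dose(od) = a*od + b*od/(c - od), strictly increasing on [0, c).
    The inverse (dose -> od) is solved numerically and is used to produce
    synthetic optical-density films from dose rasters.
    """

    def __init__(self, a: float = 1.0, b: float = 0.5, c: float = 2.0):
        if a <= 0 or b <= 0 or c <= 0:
            raise ValueError("calibration coefficients must be positive")
        self.a, self.b, self.c = float(a), float(b), float(c)
        #: valid optical-density domain
        self.domain = (0.0, self.c * (1 - 1e-9))

    def __call__(self, od):
        od = np.asarray(od, dtype=float)
        return self.a * od + self.b * od / (self.c - od)

    def inverse(self, dose):
        dose = np.asarray(dose, dtype=float)
        flat = np.atleast_1d(dose).ravel()
        out = np.empty_like(flat)
        hi = self.domain[1]
        for i, d in enumerate(flat):
            if d <= 0:
                out[i] = 0.0
            else:
                out[i] = brentq(lambda x: self(x) - d, 0.0, hi, xtol=1e-12)
        return out.reshape(np.shape(dose)) if np.ndim(dose) else float(out[0])


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _raster_grid(image_size_px, pixel_spacing_mm):
    ny, nx = image_size_px
    x = (np.arange(nx) - (nx - 1) / 2.0) * pixel_spacing_mm
    y = (np.arange(ny) - (ny - 1) / 2.0) * pixel_spacing_mm
    return np.meshgrid(x, y)


def _add_noise(values, noise_sd, rng):
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    return np.clip(values, 0.0, None)


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


# ----------------------------------------------------------------------
# generators
# ----------------------------------------------------------------------
def gen_starshot_film(spec: StarshotSpec, seed: int = 0) -> DoseImage:
    """Render a starshot film: one high-dose strip per spoke angle.

    Each strip is the line through ``center + offset * n`` with direction
    ``(cos a, sin a)`` and unit normal ``n = (-sin a, cos a)``.  Identical
    seeds give bit-identical images.
    """
    rng = np.random.default_rng(seed)
    X, Y = _raster_grid(spec.image_size_px, spec.pixel_spacing_mm)
    cx, cy = spec.center_mm
    img = np.zeros_like(X)
    half_w = spec.spoke_width_mm / 2.0
    for ang, off in zip(spec.spoke_angles_deg, spec.spoke_offsets_mm):
        th = np.deg2rad(ang)
        nx_, ny_ = -np.sin(th), np.cos(th)
        dist = nx_ * (X - cx) + ny_ * (Y - cy) - off
        img += _logistic((half_w - np.abs(dist)) / spec.edge_mm)
    img = _add_noise(img, spec.noise_sd, rng)
    return DoseImage(img, spec.pixel_spacing_mm, units="dose")


def gen_picketfence_film(
    nominal_positions_cm: Sequence[float],
    injected_shifts_mm: Sequence[float],
    *,
    pixel_spacing_mm: float = 0.5,
    image_size_px: tuple[int, int] = (64, 560),
    strip_sigma_mm: float = 2.5,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseImage:
    """Picket-fence film: one in-plane strip per nominal cross-plane position.

    Strips have a Gaussian cross-section (a film-blur surrogate) so each
    picket has a smooth, unique peak at ``10*nominal + shift`` mm, matching
    the sub-pixel parabolic peak localisation used by the analysis.
    """
    nominal = np.asarray(nominal_positions_cm, dtype=float)
    shifts = np.asarray(injected_shifts_mm, dtype=float)
    if nominal.shape != shifts.shape:
        raise ValueError("nominal positions and shifts must have equal length")
    centers_mm = nominal * 10.0 + shifts
    order = np.argsort(centers_mm)
    if np.any(np.diff(centers_mm[order]) < 6 * strip_sigma_mm):
        raise ValueError("strips overlap: centres closer than 6 sigma")
    rng = np.random.default_rng(seed)
    X, _ = _raster_grid(image_size_px, pixel_spacing_mm)
    if centers_mm.min() < X.min() or centers_mm.max() > X.max():
        raise ValueError("strip centres fall outside the film")
    img = np.zeros_like(X)
    for c in centers_mm:
        img += amplitude * np.exp(-((X - c) ** 2) / (2 * strip_sigma_mm**2))
    img = _add_noise(img, noise_sd, rng)
    return DoseImage(img, pixel_spacing_mm, units="dose")


def field_profile_value(x_mm: np.ndarray, spec: ProfileSpec) -> np.ndarray:
    """Noiseless profile model: logistic edges at +-width/2, optional dome."""
    w2 = spec.nominal_width_cm * 10.0 / 2.0
    s = spec.edge_scale_mm
    plateau = _logistic((x_mm + w2) / s) * _logistic((w2 - x_mm) / s)
    if spec.fff_peak_fraction > 0:
        dome = np.where(
            np.abs(x_mm) < w2,
            1.0 + spec.fff_peak_fraction * (1.0 - (x_mm / w2) ** 2),
            1.0,
        )
        plateau = plateau * dome
    return plateau


def gen_field_profile(spec: ProfileSpec, seed: int = 0, axis: str = "cross_plane") -> BeamProfile:
    """Symmetric FFF-shaped beam profile sampled on a regular grid.

    The FWHM of the noiseless profile equals ``nominal_width_cm`` to within
    one sampling step.
    """
    rng = np.random.default_rng(seed)
    w2 = spec.nominal_width_cm * 10.0 / 2.0
    half_span = w2 + max(10.0 * spec.edge_scale_mm, 30.0)
    n = int(np.floor(half_span / spec.sampling_step_mm))
    x_mm = np.arange(-n, n + 1) * spec.sampling_step_mm
    vals = field_profile_value(x_mm, spec)
    if spec.noise_sd > 0:
        vals = np.clip(vals + rng.normal(0.0, spec.noise_sd, size=vals.shape), 0.0, None)
    return BeamProfile(x_mm / 10.0, vals, axis=axis)


def gen_spectrum(spec: SpectrumSpec, seed: int = 0) -> SpectrumProfile:
    """Resonance peak around the central frequency.

    The noiseless magnitude peak has FWHM equal to ``spec.fwhm_hz`` (exact
    for both line shapes, up to the sampling step).
    """
    rng = np.random.default_rng(seed)
    half_span = spec.span_fwhm * spec.fwhm_hz
    n = int(np.floor(half_span / spec.sampling_step_hz))
    f = spec.center_frequency_hz + np.arange(-n, n + 1) * spec.sampling_step_hz
    df = f - spec.center_frequency_hz
    if spec.line_shape == "gaussian":
        sigma = spec.fwhm_hz / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        mag = np.exp(-(df**2) / (2 * sigma**2))
    else:
        g = spec.fwhm_hz / 2.0
        mag = g**2 / (df**2 + g**2)
    if spec.noise_sd > 0:
        mag = np.clip(mag + rng.normal(0.0, spec.noise_sd, size=mag.shape), 0.0, None)
    return SpectrumProfile(f, mag, nominal_f0_hz=spec.center_frequency_hz)


def gen_uniform_phantom_image(
    mean: float,
    noise_sd: float,
    size: tuple[int, int] = (256, 256),
    seed: int = 0,
    pixel_spacing_mm: float = 1.0,
) -> GrayImage:
    """Uniform-sphere phantom slice: constant signal plus additive noise."""
    rng = np.random.default_rng(seed)
    vals = np.full(size, float(mean))
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=size)
    return GrayImage(np.clip(vals, 0.0, None), pixel_spacing_mm, units="raw")


def gen_grid_phantom_image(spec: GridPhantomSpec) -> GridPhantomImage:
    """Grid phantom with Gaussian markers displaced by the distortion field."""
    nominal = spec.nominal_positions_mm()
    if spec.distortion_field is None:
        true = nominal.copy()
    else:
        disp = np.asarray(spec.distortion_field(nominal), dtype=float)
        if disp.shape != nominal.shape:
            raise ValueError("distortion field must return one displacement per marker")
        true = nominal + disp
    pad = 4 * spec.marker_sigma_mm + spec.marker_spacing_mm / 2.0
    half_x = spec.extent_mm[0] / 2.0 + pad
    half_y = spec.extent_mm[1] / 2.0 + pad
    nx = 2 * int(np.ceil(half_x / spec.pixel_spacing_mm)) + 1
    ny = 2 * int(np.ceil(half_y / spec.pixel_spacing_mm)) + 1
    X, Y = _raster_grid((ny, nx), spec.pixel_spacing_mm)
    img = np.zeros_like(X)
    s2 = 2 * spec.marker_sigma_mm**2
    for tx, ty in true:
        # restrict each blob to a local window for speed
        m = (np.abs(X[0] - tx) < 5 * spec.marker_sigma_mm).nonzero()[0]
        r = (np.abs(Y[:, 0] - ty) < 5 * spec.marker_sigma_mm).nonzero()[0]
        if m.size == 0 or r.size == 0:
            continue
        sl = np.ix_(r, m)
        img[sl] += np.exp(-((X[sl] - tx) ** 2 + (Y[sl] - ty) ** 2) / s2)
    image = GrayImage(img, spec.pixel_spacing_mm, units="raw")
    return GridPhantomImage(image=image, nominal_mm=nominal, true_mm=true)


def gen_motion_trace(spec: MotionSpec, seed: int = 0) -> MotionTrace:
    """Sinusoidal target motion with a latency-delayed gated beam.

    The beam is ON whenever the *delayed* target position lies inside the
    gating boundary: ``beam_on(t) = |p(t - latency)| <= boundary``.  Ground
    truth (latency, boundary) is recorded in ``trace.meta``.

    The motion starts at a random phase drawn from ``seed``: the cine frame
    clock is not synchronised to the phantom in practice, and a random
    phase prevents the frame-quantisation error from being identical at
    every gating event when the period is a multiple of the frame interval.
    """
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2 * np.pi)
    dt = 1.0 / spec.frame_rate_fps
    t = np.arange(0.0, spec.duration_s, dt)
    w = 2 * np.pi / spec.period_s
    pos = spec.amplitude_mm * np.sin(w * t + phase)
    delayed = spec.amplitude_mm * np.sin(w * (t - spec.injected_latency_s) + phase)
    beam_on = np.abs(delayed) <= spec.gating_boundary_mm
    return MotionTrace(
        t,
        pos,
        beam_on,
        meta={
            "injected_latency_s": spec.injected_latency_s,
            "gating_boundary_mm": spec.gating_boundary_mm,
            "frame_rate_fps": spec.frame_rate_fps,
        },
    )


def gen_leakage_film(
    transmission_frac: float = 0.0008,
    interleaf_peak_frac: float = 0.0030,
    *,
    leaf_pitch_mm: float = 8.3,
    stripe_sigma_mm: float = 1.0,
    reference_dose: float = 1.0,
    pixel_spacing_mm: float = 1.0,
    image_size_px: tuple[int, int] = (340, 340),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseImage:
    """Closed-MLC leakage map: uniform transmission plus interleaf stripes.

    Stripes run along the leaf-travel (cross-plane) axis, spaced at the leaf
    pitch along y.  Dose is expressed in the same units as the open
    reference film (``reference_dose`` at the central axis), so injected
    fractions are the per-film (not per-MU) dose ratios.
    """
    rng = np.random.default_rng(seed)
    X, Y = _raster_grid(image_size_px, pixel_spacing_mm)
    img = np.full_like(X, transmission_frac * reference_dose)
    y0 = Y.min() + leaf_pitch_mm / 2.0
    centers = np.arange(y0, Y.max(), leaf_pitch_mm)
    amp = (interleaf_peak_frac - transmission_frac) * reference_dose
    for cy in centers:
        img += amp * np.exp(-((Y - cy) ** 2) / (2 * stripe_sigma_mm**2))
    img = _add_noise(img, noise_sd, rng)
    return DoseImage(img, pixel_spacing_mm, units="dose")


def gen_field_film(
    width_cm: float,
    height_cm: float,
    *,
    pixel_spacing_mm: float = 0.1,
    edge_mm: float = 0.3,
    amplitude: float = 1.0,
    margin_mm: float = 6.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseImage:
    """Small rectangular field film (logistic edges) for film field-size tests."""
    rng = np.random.default_rng(seed)
    w2, h2 = width_cm * 10.0 / 2.0, height_cm * 10.0 / 2.0
    nx = 2 * int(np.ceil((w2 + margin_mm) / pixel_spacing_mm)) + 1
    ny = 2 * int(np.ceil((h2 + margin_mm) / pixel_spacing_mm)) + 1
    X, Y = _raster_grid((ny, nx), pixel_spacing_mm)
    fx = _logistic((X + w2) / edge_mm) * _logistic((w2 - X) / edge_mm)
    fy = _logistic((Y + h2) / edge_mm) * _logistic((h2 - Y) / edge_mm)
    img = _add_noise(amplitude * fx * fy, noise_sd, rng)
    return DoseImage(img, pixel_spacing_mm, units="dose")
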