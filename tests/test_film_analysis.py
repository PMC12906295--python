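"""Film analyses: calibration, starshot, picket fence, leakage, field size."""
import numpy as np
import pytest

from conftest import LEAF_SHIFTS_MM, LEAF_STATS_MM, PICKET_NOMINALS_CM
from mrlqa import (
    DoseImage,
    analyze_leakage,
    analyze_picketfence,
    analyze_starshot,
    calibrate_film,
    chebyshev_center,
    leaf_shift_stats,
    measure_field_size_film,
)
from mrlqa.film_analysis import SpokeLine, _window_means
from mrlqa.synthetic_data import (
    RationalCalibration,
    StarshotSpec,
    gen_field_film,
    gen_picketfence_film,
    gen_starshot_film,
)


def line_from_angle_offset(angle_deg, offset, center=(0.0, 0.0)):
    """Line with direction angle_deg displaced by offset along its normal."""
    th = np.deg2rad(angle_deg)
    n = np.array([-np.sin(th), np.cos(th)])
    d = n @ np.asarray(center) + offset
    return SpokeLine(float(n[0]), float(n[1]), float(d))


def brute_force_center(lines, span=3.0, step=0.01, around=(0.0, 0.0)):
    """Grid-search oracle for the minimax (Chebyshev) centre."""
    g = np.arange(-span, span + step / 2, step)
    X, Y = np.meshgrid(g + around[0], g + around[1])
    worst = np.zeros_like(X)
    for ln in lines:
        worst = np.maximum(worst, np.abs(ln.nx * X + ln.ny * Y - ln.d))
    k = np.unravel_index(np.argmin(worst), worst.shape)
    return (X[k], Y[k]), worst[k]


# ----------------------------------------------------------------------
# calibration
# ----------------------------------------------------------------------
def test_calibrate_identity_and_linear():
    od = DoseImage(np.full((8, 8), 0.5), 1.0, units="od")
    out = calibrate_film(od, lambda v: v)
    assert np.array_equal(out.values, od.values) and out.units == "dose"
    out2 = calibrate_film(od, lambda v: 2.0 * v)
    assert np.allclose(out2.values, 1.0)
    assert out2.pixel_spacing_mm == od.pixel_spacing_mm
    assert out2.origin_mm == od.origin_mm


def test_calibrate_rational_round_trip():
    curve = RationalCalibration(a=1.0, b=0.5, c=2.0)
    dose = np.linspace(0.1, 4.0, 64).reshape(8, 8)
    od_img = DoseImage(curve.inverse(dose), 1.0, units="od")
    out = calibrate_film(od_img, curve)
    assert np.max(np.abs(out.values - dose)) < 1e-9


def test_calibrate_rejects_out_of_domain_and_nonmonotone():
    curve = RationalCalibration(c=2.0)
    bad = DoseImage(np.full((4, 4), 2.5), 1.0, units="od")
    with pytest.raises(ValueError, match="domain"):
        calibrate_film(bad, curve)
    od = DoseImage(np.linspace(0, 1, 16).reshape(4, 4), 1.0, units="od")
    with pytest.raises(ValueError, match="monotone"):
        calibrate_film(od, lambda v: np.sin(10 * v))
    with pytest.raises(ValueError, match="optical-density"):
        calibrate_film(DoseImage(np.ones((4, 4)), 1.0, units="dose"), lambda v: v)


# ----------------------------------------------------------------------
# starshot
# ----------------------------------------------------------------------
def test_starshot_concurrent_spokes_radius_below_half_pixel():
    spec = StarshotSpec()  # all offsets zero: concurrent lines
    res = analyze_starshot(gen_starshot_film(spec, 1), 5)
    assert res.radius_mm <= 0.5 * spec.pixel_spacing_mm
    assert np.hypot(*res.center_mm) <= 0.5 * spec.pixel_spacing_mm
    assert res.n_spokes == 5 and len(res.spoke_lines) == 5


@pytest.mark.parametrize("radius", [0.6, 1.0])
def test_starshot_recovers_tangent_circle(radius):
    # spokes all offset by +r along their normals are tangent to a circle
    # of radius r about the centre: the analytic oracle construction
    spec = StarshotSpec(spoke_offsets_mm=(radius,) * 5, center_mm=(1.0, -0.5))
    res = analyze_starshot(gen_starshot_film(spec, 2), 5)
    half_px = 0.5 * spec.pixel_spacing_mm
    assert res.radius_mm == pytest.approx(radius, abs=half_px)
    assert res.center_mm[0] == pytest.approx(1.0, abs=half_px)
    assert res.center_mm[1] == pytest.approx(-0.5, abs=half_px)


def test_starshot_three_tangent_lines_analytic():
    # normals must positively span the plane for the constructed circle to
    # be the inscribed (minimax) circle, hence angles 120 deg apart
    lines = [line_from_angle_offset(a, 1.0, center=(0.5, 0.2)) for a in (0.0, 120.0, 240.0)]
    center, radius = chebyshev_center(lines)
    assert radius == pytest.approx(1.0, abs=1e-6)
    assert center == pytest.approx((0.5, 0.2), abs=1e-6)


def test_minimax_center_matches_brute_force_grid(rng):
    for _ in range(20):
        n = rng.integers(3, 8)
        angles = np.sort(rng.uniform(0, 180, n))
        while np.min(np.diff(np.concatenate([angles, [angles[0] + 180]]))) < 10:
            angles = np.sort(rng.uniform(0, 180, n))
        offsets = rng.uniform(-1.5, 1.5, n)
        lines = [line_from_angle_offset(a, o) for a, o in zip(angles, offsets)]
        center, radius = chebyshev_center(lines)
        # exhaustive 0.01 mm grid around the candidate: no grid point may
        # beat it, and a grid point must come within grid resolution of it
        bf_center, bf_radius = brute_force_center(lines, around=center)
        assert radius <= bf_radius + 1e-9
        assert bf_radius - radius <= 0.02


def test_starshot_radius_invariant_under_rotation():
    base = StarshotSpec(spoke_offsets_mm=(0.8,) * 5)
    r0 = analyze_starshot(gen_starshot_film(base, 3), 5).radius_mm
    rotated = StarshotSpec(
        spoke_angles_deg=tuple(a + 17.0 for a in base.spoke_angles_deg),
        spoke_offsets_mm=(0.8,) * 5,
    )
    r1 = analyze_starshot(gen_starshot_film(rotated, 3), 5).radius_mm
    assert abs(r0 - r1) <= 0.1


def test_starshot_reports_missing_spokes():
    spec = StarshotSpec(spoke_angles_deg=(0.0, 60.0, 120.0))
    with pytest.raises(ValueError, match="crossings"):
        analyze_starshot(gen_starshot_film(spec, 0), 5)


# ----------------------------------------------------------------------
# picket fence
# ----------------------------------------------------------------------
def test_picketfence_zero_shifts():
    film = gen_picketfence_film(PICKET_NOMINALS_CM, [0.0] * 7)
    res = analyze_picketfence(film, PICKET_NOMINALS_CM)
    assert np.max(np.abs(res.shifts_mm)) <= 0.5 * film.pixel_spacing_mm
    assert res.sd_shift_mm == pytest.approx(0.0, abs=0.05)


@pytest.mark.parametrize("gantry", [0, 90, 180, 270])
def test_picketfence_reproduces_leaf_shift_table(gantry):
    film = gen_picketfence_film(PICKET_NOMINALS_CM, LEAF_SHIFTS_MM[gantry])
    res = analyze_picketfence(film, PICKET_NOMINALS_CM)
    mean, sd = LEAF_STATS_MM[gantry]
    assert round(res.mean_shift_mm, 2) == pytest.approx(mean, abs=0.01)
    assert round(res.sd_shift_mm, 2) == pytest.approx(sd, abs=0.01)


def test_picketfence_random_shift_recovery():
    rng = np.random.default_rng(99)
    for trial in range(100):
        shifts = rng.uniform(-1.0, 1.0, len(PICKET_NOMINALS_CM))
        film = gen_picketfence_film(PICKET_NOMINALS_CM, shifts, seed=trial)
        res = analyze_picketfence(film, PICKET_NOMINALS_CM)
        assert np.max(np.abs(np.asarray(res.shifts_mm) - shifts)) <= 0.5 * film.pixel_spacing_mm


def test_picketfence_missing_strip_names_nominal():
    film = gen_picketfence_film([0.0, 4.0], [0.0, 0.0])
    with pytest.raises(ValueError, match="-8"):
        analyze_picketfence(film, [0.0, 4.0, -8.0])


def test_leaf_shift_stats():
    assert leaf_shift_stats([0.0, 0.0, 0.0]) == (0.0, 0.0)
    mean, sd = leaf_shift_stats(LEAF_SHIFTS_MM[0])
    assert (round(mean, 2), round(sd, 2)) == (0.03, 0.28)
    mean, sd = leaf_shift_stats(LEAF_SHIFTS_MM[270])
    assert (round(mean, 2), round(sd, 2)) == (0.01, 0.24)
    with pytest.raises(ValueError):
        leaf_shift_stats([0.1])


# ----------------------------------------------------------------------
# MLC leakage
# ----------------------------------------------------------------------
def uniform_image(value, size_px=320, spacing=1.0):
    return DoseImage(np.full((size_px, size_px), float(value)), spacing)


def test_leakage_uniform_film_arithmetic():
    res = analyze_leakage(uniform_image(1.0), uniform_image(1.0), 10_000, 100)
    assert res.avg_leakage_pct == pytest.approx(1.0)
    assert res.max_leakage_pct == pytest.approx(1.0)

    res2 = analyze_leakage(uniform_image(0.08), uniform_image(1.0), 10_000, 100)
    assert res2.avg_leakage_pct == pytest.approx(0.08)


def test_leakage_invariant_under_joint_dose_rescaling():
    rng = np.random.default_rng(5)
    leak = DoseImage(0.05 + 0.01 * rng.random((320, 320)), 1.0)
    ref = DoseImage(0.9 + 0.1 * rng.random((320, 320)), 1.0)
    a = analyze_leakage(leak, ref, 10_000, 100)
    k = 3.7
    b = analyze_leakage(
        DoseImage(k * leak.values, 1.0), DoseImage(k * ref.values, 1.0), 10_000, 100
    )
    assert a.avg_leakage_pct == pytest.approx(b.avg_leakage_pct)
    assert a.max_leakage_pct == pytest.approx(b.max_leakage_pct)


def test_leakage_sliding_window_max_matches_exhaustive(rng):
    sub = rng.random((50, 50))
    wy, wx = 7, 5
    means = _window_means(sub, wy, wx)
    brute = np.array(
        [
            [sub[i : i + wy, j : j + wx].mean() for j in range(50 - wx + 1)]
            for i in range(50 - wy + 1)
        ]
    )
    assert np.allclose(means, brute, atol=1e-12)


def test_leakage_roi_exceeding_bounds_rejected():
    with pytest.raises(ValueError, match="bounds"):
        analyze_leakage(uniform_image(1.0, size_px=100), uniform_image(1.0), 1e4, 100,
                        roi_mm=(300.0, 300.0))


def test_leakage_max_window_localization():
    vals = np.full((320, 320), 0.05)
    vals[200:210, 240:250] = 0.5  # hot 10x10 mm square
    res = analyze_leakage(DoseImage(vals, 1.0), uniform_image(1.0), 10_000, 100)
    cx, cy = res.max_roi_center_mm
    assert abs(cx - (244.5 - 159.5)) <= 1.0 and abs(cy - (204.5 - 159.5)) <= 1.0
    assert res.max_leakage_pct > res.avg_leakage_pct


# ----------------------------------------------------------------------
# film field size
# ----------------------------------------------------------------------
def test_film_field_size_square():
    img = gen_field_film(0.83, 0.83)
    res = measure_field_size_film(img)
    assert res.cross_plane_cm == pytest.approx(0.83, abs=0.02)
    assert res.in_plane_cm == pytest.approx(0.83, abs=0.02)


def test_film_field_size_rectangle_and_scale_invariance():
    img = gen_field_film(0.34, 0.80)
    res = measure_field_size_film(img)
    assert res.cross_plane_cm == pytest.approx(0.34, abs=0.02)
    assert res.in_plane_cm == pytest.approx(0.80, abs=0.02)
    scaled = DoseImage(img.values * 7.3, img.pixel_spacing_mm)
    res2 = measure_field_size_film(scaled)
    assert res2.cross_plane_cm == pytest.approx(res.cross_plane_cm, abs=1e-12)


def test_film_field_size_requires_signal():
    with pytest.raises(ValueError):
        measure_field_size_film(DoseImage(np.zeros((16, 16)), 1.0))
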