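"""MR-side QA: B0 homogeneity, SNR/uniformity, ACR metrics, distortion."""
import numpy as np
import pytest

from mrlqa import (
    DoseImage,
    Roi,
    check_central_frequency,
    percent_integral_uniformity,
    percent_signal_ghosting,
    slice_position,
    slice_thickness,
    snr,
    spatial_integrity,
    spectral_homogeneity,
    uniformity,
)
from mrlqa.containers import SpectrumProfile
from mrlqa.synthetic_data import (
    GridPhantomSpec,
    SpectrumSpec,
    gen_grid_phantom_image,
    gen_spectrum,
    gen_uniform_phantom_image,
)


# ----------------------------------------------------------------------
# B0 homogeneity
# ----------------------------------------------------------------------
@pytest.mark.parametrize("fwhm_hz,expected_ppm", [(83.21, 5.7), (25.68, 1.7)])
def test_homogeneity_reported_ppm(fwhm_hz, expected_ppm):
    cf = 14_713_851.0
    sp = gen_spectrum(SpectrumSpec(center_frequency_hz=cf, fwhm_hz=fwhm_hz,
                                   sampling_step_hz=fwhm_hz / 50.0))
    res = spectral_homogeneity(sp, cf_mode="nominal")
    assert round(res.ppm, 1) == expected_ppm
    assert res.within_tolerance == (expected_ppm <= 5.0)


def test_homogeneity_one_ppm_identity():
    cf = 14_701_760.0
    width = cf * 1e-6
    sp = gen_spectrum(SpectrumSpec(center_frequency_hz=cf, fwhm_hz=width,
                                   sampling_step_hz=width / 50.0))
    assert spectral_homogeneity(sp).ppm == pytest.approx(1.0, abs=0.01)


def test_homogeneity_invariances():
    sp = gen_spectrum(SpectrumSpec(fwhm_hz=60.0, sampling_step_hz=0.5))
    r1 = spectral_homogeneity(sp)
    r2 = spectral_homogeneity(SpectrumProfile(sp.frequency_hz, 5.0 * sp.magnitude,
                                              nominal_f0_hz=sp.nominal_f0_hz))
    assert r2.ppm == pytest.approx(r1.ppm, rel=1e-9)  # magnitude-scale invariant
    r3 = spectral_homogeneity(gen_spectrum(SpectrumSpec(fwhm_hz=120.0, sampling_step_hz=0.5)))
    assert r3.ppm == pytest.approx(2 * r1.ppm, rel=0.02)  # proportional to FWHM


def test_homogeneity_cf_modes_and_errors():
    sp = gen_spectrum(SpectrumSpec(center_frequency_hz=14_713_851.0, fwhm_hz=80.0,
                                   sampling_step_hz=1.0))
    peak = spectral_homogeneity(sp, cf_mode="peak")
    assert peak.cf_used_hz == pytest.approx(14_713_851.0, abs=1.0)
    flat = SpectrumProfile(np.arange(100.0), np.ones(100))
    with pytest.raises(ValueError, match="baseline"):
        spectral_homogeneity(flat)


def test_central_frequency_window():
    assert check_central_frequency(14_701_760.0)
    assert check_central_frequency(14_686_760.0)  # boundary is inclusive
    assert check_central_frequency(14_716_760.0)
    assert not check_central_frequency(14_680_000.0)


# ----------------------------------------------------------------------
# SNR / uniformity
# ----------------------------------------------------------------------
def test_snr_known_moments():
    img = gen_uniform_phantom_image(100.0, 5.0, (240, 240), seed=7)
    val = snr(img, Roi((0, 0), (80, 80)), Roi((90, 90), (50, 50)))
    assert val == pytest.approx(0.66 * 100.0 / 5.0, rel=0.05)


def test_snr_zero_signal_and_scale_invariance():
    img = gen_uniform_phantom_image(100.0, 5.0, (240, 240), seed=7)
    sig, noi = Roi((0, 0), (80, 80)), Roi((90, 90), (50, 50))
    a = snr(img, sig, noi)
    scaled = DoseImage(img.values * 3.0, img.pixel_spacing_mm, units="raw")
    assert snr(scaled, sig, noi) == pytest.approx(a, rel=1e-9)
    flat = DoseImage(np.zeros((100, 100)), 1.0, units="raw")
    with pytest.raises(ValueError, match="noise"):
        snr(flat, sig, sig)


def test_uniformity_closed_forms():
    const = gen_uniform_phantom_image(100.0, 0.0, (60, 60))
    assert uniformity(const, Roi((0, 0), (40, 40))) == pytest.approx(100.0)
    # two-level image: filtered extrema 3 and 1 -> 100*(1 - 2/4) = 50
    vals = np.ones((60, 60))
    vals[:, 30:] = 3.0
    two = DoseImage(vals, 1.0, units="raw")
    assert uniformity(two, Roi((0, 0), (40, 40)), prefilter_mm=1.0) == pytest.approx(50.0)


def test_uniformity_linear_gradient():
    # ROI spanning [90, 110]: 100*(1 - 20/200) = 90, up to filter edge effects
    vals = np.tile(np.linspace(80.0, 120.0, 201), (201, 1))
    img = DoseImage(vals, 1.0, units="raw")
    val = uniformity(img, Roi((0, 0), (100, 100)), prefilter_mm=3.0)
    assert val == pytest.approx(90.0, abs=0.5)


def test_uniformity_scale_invariance():
    img = gen_uniform_phantom_image(100.0, 2.0, (80, 80), seed=1)
    roi = Roi((0, 0), (50, 50))
    a = uniformity(img, roi)
    b = uniformity(DoseImage(4.0 * img.values, 1.0, units="raw"), roi)
    assert a == pytest.approx(b, rel=1e-9)


# ----------------------------------------------------------------------
# ACR metrics
# ----------------------------------------------------------------------
def _ghost_setup():
    center = Roi((0, 0), (60, 60))
    edges = {
        "top": Roi((0, -110), (40, 10)),
        "bottom": Roi((0, 110), (40, 10)),
        "left": Roi((-110, 0), (10, 40)),
        "right": Roi((110, 0), (10, 40)),
    }
    return center, edges


def test_ghosting_symmetric_background_is_zero():
    img = gen_uniform_phantom_image(100.0, 0.0, (256, 256))
    center, edges = _ghost_setup()
    assert percent_signal_ghosting(img, center, edges) == pytest.approx(0.0)


def test_ghosting_arithmetic_and_injected_stripe():
    img = gen_uniform_phantom_image(100.0, 0.0, (256, 256))
    center, edges = _ghost_setup()
    vals = img.values.copy()
    # ghost stripe raises only the top/bottom ROI rows by 2 units
    for roi in (edges["top"], edges["bottom"]):
        vals[roi.mask(img)] += 2.0
    ghosted = DoseImage(vals, 1.0, units="raw")
    # ((2+2) - (0+0)) / (2*100) relative to the uniform 100 background = 0.02
    assert percent_signal_ghosting(ghosted, center, edges) == pytest.approx(
        (2.0 + 2.0) / (2.0 * 100.0), abs=1e-9
    )
    with pytest.raises(ValueError, match="missing"):
        percent_signal_ghosting(img, center, {"top": edges["top"]})


def test_percent_integral_uniformity():
    img = gen_uniform_phantom_image(200.0, 0.0, (120, 120))
    roi = Roi((0, 0), (80, 80))
    assert percent_integral_uniformity(img, roi) == pytest.approx(100.0)
    vals = img.values.copy()
    vals[40:80, 40:80] = 180.0  # low patch larger than the 10 mm window
    piu = percent_integral_uniformity(DoseImage(vals, 1.0, units="raw"), roi)
    assert piu == pytest.approx(100 * (1 - 20 / 380), abs=0.5)


def test_slice_thickness_formula():
    assert slice_thickness(50.0, 50.0) == pytest.approx(5.0)
    assert slice_thickness(60.0, 50.0) == pytest.approx(0.2 * 3000.0 / 110.0)
    with pytest.raises(ValueError):
        slice_thickness(0.0, 50.0)


def test_slice_position_half_difference():
    assert slice_position(1.1) == pytest.approx(0.55)
    assert slice_position(0.0) == 0.0


# ----------------------------------------------------------------------
# spatial integrity
# ----------------------------------------------------------------------
def test_spatial_integrity_identity():
    spec = GridPhantomSpec()
    gp = gen_grid_phantom_image(spec)
    res = spatial_integrity(gp.image, spec)
    assert res.mean_mm <= 0.5 * spec.pixel_spacing_mm
    assert res.max_mm >= res.mean_mm >= 0


def test_spatial_integrity_uniform_translation():
    shift = np.array([0.5, 0.0])
    spec = GridPhantomSpec(distortion_field=lambda xy: np.tile(shift, (len(xy), 1)))
    gp = gen_grid_phantom_image(spec)
    res = spatial_integrity(gp.image, GridPhantomSpec())
    assert res.mean_mm == pytest.approx(0.5, abs=0.1)


def test_spatial_integrity_radial_field_per_bin():
    a = 2e-3  # radial distortion d(r) = a * r, outward

    def field(xy):
        r = np.linalg.norm(xy, axis=1, keepdims=True)
        return a * r * np.where(r > 0, xy / np.maximum(r, 1e-12), 0.0)

    spec = GridPhantomSpec(distortion_field=field)
    gp = gen_grid_phantom_image(spec)
    res = spatial_integrity(gp.image, GridPhantomSpec(), dsv_radii_mm=(60.0, 120.0, 200.0))
    nominal = GridPhantomSpec().nominal_positions_mm()
    radii = np.linalg.norm(nominal, axis=1)
    for (lo, hi), got in res.radius_bins.items():
        sel = (radii >= lo) & (radii < hi)
        assert got == pytest.approx(a * radii[sel].mean(), abs=0.5 * spec.pixel_spacing_mm)


def test_spatial_integrity_detection_failure_lists_missing():
    spec = GridPhantomSpec()
    gp = gen_grid_phantom_image(spec)
    vals = gp.image.values.copy()
    vals[:, : vals.shape[1] // 2] = 0.0  # wipe half the markers
    broken = DoseImage(vals, spec.pixel_spacing_mm, units="raw")
    with pytest.raises(ValueError, match="markers detected"):
        spatial_integrity(broken, spec)
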