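# Methods

This note documents the models, conventions and numerical choices behind
`mrlqa`, and what the synthetic-data generators do and do not emulate.

## Coordinate conventions

All rasters use millimetre physical coordinates with the origin at the
image centre; x is the cross-plane (lateral) axis along columns, y the
in-plane (longitudinal) axis along rows. Three scanner frames are
supported for 3-vectors: the Linac frame (IEC 61217), the MRI frame
(DICOM) and the laser frame (DICOM, sharing the MRI axis convention).
For a head-first-supine patient, Left/Superior/Anterior map to
(+X, +Y, +Z) in the Linac frame and (+X, −Z, +Y) in the MRI/laser frames,
so Linac→MRI is (x, y, z) → (x, z, −y). Conversions are orthonormal and
round-trip exactly; isocenter-shift composition commutes with them.

## Starshot isocentricity

The radiation isocenter of a starshot film is defined as the centre of the
minimum circle tangent to all spoke centre-lines. The implementation:

1. seeds at the intensity-weighted image centroid;
2. samples the film on two concentric circles (0.45 and 0.8 of the border
   distance, 4096 angular samples, bilinear interpolation) and reduces each
   strip crossing to an intensity-weighted angular centroid — two circles
   give four points per spoke and robustness to a mis-seeded centre;
3. pairs crossings across circles by angular proximity, groups the rays
   into spokes by direction modulo 180° (split at the largest circular
   gaps), and fits each spoke by orthogonal (total-least-squares)
   regression;
4. solves the Chebyshev centre `min_c max_i |n_i·c − d_i|` as a linear
   program (HiGHS); among centres attaining the optimum a least-squares
   polish (SLSQP) breaks ties.

The minimax solution equals an exhaustive 0.01 mm grid search on random
line sets, and tangent-circle constructions (all spokes offset +r along
their normals) are recovered to within half a pixel. Note that a
constructed tangent circle is the *minimax* circle only when the spoke
normals positively span the plane — automatic for ≥ 5 spokes at 72°
increments, but a 3-spoke construction needs directions ~120° apart.

## Picket fence

Pickets are located on the cross-plane projection (mean over rows) by
3-point parabolic interpolation around the per-nominal window maximum
(window ± 15 mm). Shifts are detected − nominal; statistics are the
arithmetic mean and the **sample (n−1) SD** — the published per-gantry
mean ± SD values of the leaf-shift tables reproduce only with the n−1
denominator. Synthetic strips use a Gaussian cross-section (σ = 2.5 mm), a
film-blur surrogate that gives each picket a smooth unique maximum matched
to the parabolic estimator; real films have flat-topped strips whose
plateau would need edge-based localisation instead.

## MLC transmission / leakage

Average leakage is the mean dose in a 300 × 300 mm ROI centred on the
axis; maximum leakage is the largest mean over sliding 10 × 10 mm windows
(integral-image window sums, windows fully contained in the ROI — the
published procedure names a window "centred on the peak leakage region"
without a search rule, so an exhaustive pixel-resolution slide is used).
Both are normalised per MU to the reference field's central-axis dose
(mean over a 10 mm central window): `% = 100·(D/MU)/(D_ref/MU_ref)`.
Percentages are invariant under joint rescaling of both films' dose units.

## Film calibration and field size

`calibrate_film` applies any strictly monotone OD→dose mapping pixelwise,
rejecting out-of-domain optical densities with a range report. The
synthetic calibration layer is a monotone rational curve
`dose = a·od + b·od/(c − od)`; its numerical inverse produces OD films for
round-trip tests (max error < 1e-9). Small-field film size is the FWHM of
the central cross-plane and in-plane profiles through the intensity
centroid — FWHM is scale-free, so film-dose units need not be absolute.

## Profiles: FWHM, penumbra, flatness/symmetry, FOF

Half-maximum and 20/80 % crossings are linearly interpolated; FWHM
requires exactly two crossings (multi-lobe data are rejected). Penumbra is
reported per edge plus the mean, and comparisons use the mean since the
published per-direction tables do not state which edge they quote. With
`normalize=True` (default; the convention for fields ≥ 4.15 cm) the
profile is rescaled to 100 at its maximum before thresholding; with
`normalize=False` the values are taken as already on a percent scale.
A logistic edge of scale s has a closed-form 20–80 % width `2·s·ln 4`,
which the tests use as an analytic oracle. Optional moving-average
smoothing is available but off by default.

Flatness is the pointwise difference F = M − TPS and symmetry
S = M(−OAP) − M(+OAP) per ± pair, both checked against ± 2 %; |S| is used
for the verdict. Output factors divide each field's averaged replicate
reading by the reference field's average (reference FOF ≡ 1), and percent
differences use the TPS as denominator rounded to 1 dp — the convention
validated against the published comparison tables (the measured-denominator
alternative does not reproduce them; the smallest-field row reproduces only
from unrounded raw inputs and is not asserted).

## Gamma index

Per reference point, `γ = min √((ΔD/ΔD_c)² + (Δr/DTA)²)` over the
evaluated distribution bilinearly resampled to a grid no coarser than
0.1·DTA; the native nodes are kept on the fine grid (exact subdivision), so
identical distributions give γ ≡ 0 and a uniform +3 % offset at 3 %/3 mm
sits exactly on the γ = 1 boundary. The search radius is 3·DTA — beyond
it the distance term alone exceeds 3, so the restriction cannot change any
γ near the pass threshold. Global normalisation scales the criterion by
the reference maximum; local by each point's own dose (zero-dose points
are skipped under local normalisation). γ ≤ 1 passes.

## Couch attenuation

The percent forms `100·(1 − Rθ/R0)` and `100·(1 − MU/Reference)` are
provided, but the tabulated "relative attenuation" values (~1.0–1.2) are
attenuation *factors*: measured `R0/Rθ` and calculated `MU/Reference_MU`
(R0/Reference averaged over the unattenuated 90°/270° beams). The
deviation is `100·(measured − TPS)/TPS` rounded to 1 dp, which reproduces
every tabulated deviation; only this factor-plus-relative-deviation reading
does. The tolerance registry carries both the ± 3 % method tolerance and
the stricter ± 1 % results tolerance.

## Gating

Dose deviation is `100·(D_ng − D_g)/D_ng`, reported as a magnitude at
2 dp. Beam-off latency is the primary latency estimand: for each
boundary-exit event the crossing time is linearly interpolated from the
sampled |position|, the beam-off time is the midpoint of the last-on and
first-off frames (so the per-event error is at most half a frame period
and unbiased for uniformly distributed crossing phases), and the latency
is the event mean (≥ 3 events required; events whose apparent latency
exceeds 1 s are treated as mispaired and dropped). The synthetic motion is
a 12 mm, 4 s sinusoid sampled at the cine frame rate with the beam gated
on the latency-delayed position and a 3 mm boundary; the start phase is
drawn from the seed because a frame clock synchronised to the motion
period would freeze the quantisation error at a single value.

## Reference dose

`D = M · N_D,w · k_Q · k_B` per MU with k_B defaulting to 0.9957 (0.35 T,
chamber perpendicular to the field). k_Q is supplied directly or linearly
interpolated from a user-provided (%dd(10)x, k_Q) anchor table; no
chamber-specific k_Q database ships with the package, so the published
interpolated value is exercised only as an interpolation contract.

## MRI metrics

B0 homogeneity divides the magnitude-spectrum FWHM (interpolated half-max
crossings walking outward from the peak) by the central frequency:
`ppm = FWHM/f0 × 10⁶`, ≤ 5 ppm passing. The nominal (displayed) central
frequency is the default denominator, a peak-derived one is available; at
these linewidths the choice moves ppm by < 0.001. ppm values are reported
at 1 dp. SNR is the NEMA single-image form `0.66·mean_signal/SD_noise`
with the noise SD from one background ROI (the subtraction-image method is
out of scope). Uniformity and PIU apply `100·(1−(max−min)/(max+min))`
to a mean-filtered ROI (3 mm for uniformity, 10 mm window for PIU).
Ghosting uses the standard four-ROI formula
`|(top+bottom)−(left+right)|/(2·centre)`. Slice thickness is
`0.2·(top·bottom)/(top+bottom)` from the ramp lengths and slice position
is half the bar-length difference. Spatial integrity locates each grid
marker by local centre of mass (5 % floor subtracted) within half a
marker spacing of its nominal position, requires ≥ 90 % detection, and
bins deviations radially.

## Synthetic data: what it does and does not emulate

Generators produce starshot and picket-fence films, leakage maps,
FFF-shaped profiles (logistic edges, a shallow quadratic dome of default
peak fraction 0.05), Gaussian/Lorentzian spectra, uniform and grid phantom
images, and gated motion traces — each deterministic per (spec, seed) with
ground truth recorded. Noise is additive white Gaussian only: no scanner
lateral-response or film-grain artefacts, no MR k-space effects, no MLC
tongue-and-groove structure. Default geometry: 0.5 mm film pixels (the
published procedure does not state the scanner resolution; 0.5 mm keeps
half-pixel recovery bounds at 0.25 mm), 1 mm phantom pixels, spectra
sampled at ≥ 10 points per linewidth. Passing the closure tests therefore
demonstrates correctness of the estimators under clean conditions and
their stated resolution bounds, not robustness to real-film artefacts.

## Tolerance registry

Verdicts are pure functions of (value, tolerance); printed "<" bounds are
strict, "≤ / within ±" inclusive. The 0.6 mm as-measured starshot radius,
coil SNRs and similar hardware numbers are data, not reproducible
computations; the registry only scores values the analyses produce.

## Problem sizes

Test-suite simulations use 240² px starshot films, 64 × 560 px picket
films, ≤ 320² px leakage maps, 5 × 5 gamma oracles, 100 picket-fence and
30 distortion trials and 200 latency trials — sizes chosen so the full
suite completes in seconds while keeping every recovery bound
(half-pixel, one sampling step, one frame period) meaningful.
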