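# Methods

This note records the models implemented in `mesosheet`, the
conventions adopted where the underlying optics leaves a genuine
choice, and what the synthetic tests do and do not demonstrate.

## Beam models

**Gaussian sheet.**  The sheet cross-section is the standard Gaussian
beam: waist radius `w(z) = w0 √(1 + (z/zR)²)` with `zR = π w0²/λ`.
Both equations use the *vacuum* wavelength; this is the convention that
reproduces the standard mesoscope design numbers (30 µm focal / 42–43 µm
edge thickness for a 3 mm field at 488 nm), which were evidently
computed without dividing λ by the medium index.  "Thickness" of a
Gaussian sheet means the full 1/e² diameter `2 w(z)`; where fits or
measured profiles are involved the intensity FWHM
(`w·√(2 ln 2) ≈ 1.18 w`) is reported separately, and
`GaussianSheetSpec.from_fwhm` builds a sheet from a measured thickness.
The design solver sizes the thinnest sheet whose confocal region `2 zR`
spans a requested field, giving `w0 = √(fov·λ/2π)` exactly.

**Airy sheet.**  The finite-energy Airy envelope is

    Φ(ξ,s) = Ai(s − (ξ/2)² + iaξ)
             · exp(as − aξ²/2 − iξ³/12 + ia²ξ/2 + isξ/2),

with `a` the aperture parameter (≪ 1).  The dimensionless coordinates
map to physical ones by `s = x/x0` and `ξ = y·λ/(2π·n·x0²)` — the
standard paraxial Airy scaling in a medium of index `n`.  The
transverse scale `x0` is a free calibration parameter of the
illuminator: `calibrate_transverse_scale` solves (by bisection,
tolerance 10⁻³ µm; the FWHM is strictly increasing in x0, so bisection
is exact) for the x0 that makes the simulated focal main-lobe FWHM
match a target thickness, default 7.8 µm.  At the default `a = 0.05`
this gives x0 ≈ 4.67 µm.

**Non-diffraction range.**  The finite-energy envelope decays as
`exp(−aξ²/2)`, so the quasi-invariant range depends strongly on `a`.
At `a = 0.05` and the 7.8 µm calibration, the main-lobe FWHM grows only
~5% across a 3 mm field (ξ ≈ 7); at `a = 0.1` the same span lies far
beyond the invariant range and the lobe structure washes out (growth
> 10×).  The package default is `a = 0.05`, comfortably inside the
invariant regime and consistent with the near-constant measured
thickness (7.8 → 11.1 µm) that motivates the design; the quasi-
invariance property is asserted at that default, not as a blanket claim
for all `a`.

**Theoretical field of view and axial resolution.**
`FOV = 6αλ/(n(1 − √(1 − (NA/n)²)))` evaluates to ≈ 3358 µm at the
standard parameter set (λ = 0.488 µm, n = 1.515, NA = 0.043, α = 0.7);
the commonly printed 3306 µm reflects rounding of NA and α.  The
axial-resolution estimate `r = λ/(2·NA·0.88)` gives 6.45 µm at
NA = 0.043; instruments are sometimes quoted at 7.6 µm, implying a
slightly different effective NA — the package reports the formula value
and leaves the discrepancy visible rather than adjusting parameters.

**Propagation oracle.**  `angular_spectrum_propagate` solves the
paraxial equation `i∂Φ/∂ξ + ½∂²Φ/∂s² = 0` spectrally (each mode
`e^{iks}` advances by `e^{−ik²ξ/2}`) as an independent cross-check of
the closed form.  Because the Airy beam's oscillatory tail is exactly
its high-frequency content and travels by `kξ` per unit ξ, a bare
512-point grid suffers periodic wrap-around at the 10⁻² level; the
oracle therefore transforms on an internally refined grid (6× finer,
extended ~350 dimensionless units leftward and ~80 rightward) whose
nodes contain the comparison grid exactly.  Agreement with the closed
form is then ~10⁻⁹ relative L2; the test bound is 10⁻³.

## Thickness measurement

Profiles are column means over a y-window (default 50 rows) of a sheet
cross-section image, background-subtracted (median of the lowest decile
of profile values; corner-patch estimation is available) and clipped at
zero.  The FWHM is that of the **dominant lobe only**: half-maximum
crossings are sought walking outward from the global maximum and the
search aborts if the profile rebounds by more than 5% of the peak
before crossing half-maximum (an inter-lobe minimum), so Airy side
lobes can never widen the reported thickness.  Crossings are located by
linear interpolation between samples; on unimodal profiles the result
matches a 10⁶-point brute-force search to within one pixel pitch.

Model fits use bounded nonlinear least squares with up to five jittered
restarts: a Gaussian `A·exp(−2(x−c)²/w²)+b` (FWHM = `w√(2 ln 2)`) and
the focal Airy intensity `A·Ai((x−c)/x0)²·exp(2a(x−c)/x0)+b`, fitted in
both transverse orientations (the tail direction depends on the
illuminator geometry) keeping the lower residual; `a` is clamped to
[0, 1).  Flat or non-converging inputs are flagged, never silently
replaced.  The fitted-model FWHM is evaluated on a dense grid of the
fitted curve.

**Uncertainties.**  Reported errors are the half-width of the central
68% interval of the raw FWHM over 200 bootstrap resamples of the rows
inside the averaging window.  This is a convention of this package —
published ± values on instrument measurements rarely state their
definition — and quantifies row-to-row variability, not calibration
error.

## Image-formation simulator

The phantom is a set of spherical nuclei (uniform positions and radii,
fixed brightness in expected photons) plus absorbing spherical
occluders with a per-micrometre attenuation coefficient.  For each
z-plane the sheet tracks the imaged plane; a nucleus at depth offset
Δz receives the sheet's transverse intensity at Δz, attenuated by
occluder shadows, optionally gated by a detection axial response
`exp(−Δz²/2σ_z²)` (default σ_z = 3 µm, a declared free parameter — the
detection optics' focal depth is not modelled from first principles).
Fluorescence is splatted with a lateral Gaussian of the nucleus radius
using a discretely normalized kernel, so expected photons are conserved
to < 0.1%.  Camera effects: Poisson shot noise, Gaussian read noise, a
constant baseline offset, optional hot pixels at full scale, and
clipping to the bit depth (12-bit data in 16-bit containers).  Noise
uses one seed with per-plane spawned substreams, so stacks are
bit-reproducible and plane order never changes the noise.

**Shadows and self-healing.**  Two shadow models are provided.  The
default (`"bundle"`) treats the sheet as a bundle of parallel rays
distributed across the transverse profile — side lobes included — and
re-mixed after each obstacle, which is how a non-diffracting beam
reconstructs downstream; the per-point transmission is the
profile-weighted mean of exact ray–sphere Beer–Lambert factors.  Under
this model an occluder thin relative to the Gaussian sheet casts a
weaker stripe through the Airy sheet, matching the observed asymmetry
of streaking artifacts.  The `"ray"` model attenuates a single central
ray (the textbook Beer–Lambert limit: a fully opaque occluder zeroes
its geometric shadow exactly); the two models coincide for occluders
much larger than the beam's transverse support.

**Sensor-shifting camera.**  The 9-position chip-shifting mechanism is
modelled by its sampling consequence (224 nm Nyquist pitch with 9
positions, 3× coarser with 1) and its time cost (per-plane transfer
plus 9 exposures); the sub-pixel mechanics themselves are not
simulated, since image content rather than readout kinematics is the
target.  Acquisition time is exact arithmetic:
`fov_x·ppu · fov_y·ppu · dwell · averages · planes` for point scanning,
`planes · (transfer + positions·exposure)` for the light sheet.
Whether a quoted per-frame time already includes exposure is ambiguous
in practice; exposure is added on top here, so published volume totals
are reproduced to their own "approximately" precision.

**Axial-resolution comparison.**  The simulated near-4-fold axial gain
of the Airy sheet is measured as the FWHM of the z-profile through a
single nucleus, comparing the Airy sheet (calibrated to 7.8 µm) against
a Gaussian sheet matched to the *measured* instrument thickness
(FWHM = 30 µm via `from_fwhm`; the diffraction-limited 3 mm design
would be 18 µm FWHM, but real cylindrical-lens sheets measure ~30 µm),
with the detection gate disabled so the comparison isolates the
illumination contribution — exactly what sheet-thickness profilometry
compares.  With the σ_z = 3 µm gate enabled, both responses compress
toward the detection width and the ratio drops to ~1.3; the gate is
kept for side-lobe rejection, not for this comparison.

## Restoration

`remove_outliers` replaces pixels deviating from their radius-3 disc
median by more than a threshold (default 5× the robust σ, 1.4826·MAD of
the image; bright polarity by default), leaving all other pixels
bit-identical; it is idempotent on its own output in the hot-pixel
regime it targets.  `max_projection` is the per-pixel maximum.

`lightsheet_psf` builds a separable Gaussian system PSF: lateral
σ_xy = 0.21·λ_em/NA; axially, the illumination sheet intensity
`exp(−2z²/w²)` (σ = w/2, with w the 12 µm or 25 µm "sheet waist"
deconvolution parameter).  Widefield detection redistributes defocused
light laterally but conserves it, so by default no detection axial term
multiplies in — the sheet alone sets axial discrimination, which is
what makes the 12 µm and 25 µm parameterizations genuinely different;
an explicit `detection_axial_sigma` can be supplied to model a focal-
depth gate, combining in inverse quadrature.  The PSF is normalized to
unit sum; requested supports smaller than 3σ per axis are rejected.

`cmle_deconvolve` is classical-MLE Richardson–Lucy: multiplicative
updates `e ← e · [(d/(e⊗psf)) ⊗ psf*]` on the background-subtracted
data, initialized at the data, with divisions guarded by ε = 10⁻¹².
Convolution is circular on a reflect-padded array (one PSF half-support
per axis): a circular convolution with a unit-sum kernel maps constants
to themselves and conserves total flux exactly, so the flat-input and
delta-PSF fixed points hold to machine precision and flux is constant
across iterations; PSFs wider than the transform volume are centrally
cropped and renormalized.  Iteration count is explicit — no automatic
stopping or regularization is attempted, so results are property-
checked (fixed points, flux, monotone sharpening, axial pair
separation) rather than matched to any proprietary implementation's
output.  A chunked mode processes z sub-volumes overlapping by one PSF
axial support for stacks too large to transform at once.

## Synthetic data: what it does and does not show

The generators emulate: the sheet cross-section image measured in
profilometry (beam model + constant offset + Gaussian noise), nuclei
phantoms with stripe artifacts and camera noise, and noisy 1-D
profiles.  They do not emulate refractive-index inhomogeneity,
scattering beyond Beer–Lambert absorption, aberrations, polarization,
spectral effects, or the detection optics beyond a Gaussian axial gate
and a fixed lateral splat.  Passing tests therefore demonstrate
self-consistency of the models and correctness of the numerics, and
reproduce instrument-scale numbers only where those are themselves
model-governed (design thicknesses, field of view, pixel budgets,
acquisition times, thickness ratios); they do not validate the optics
of any physical instrument.

## Problem sizes

The test suite and acceptance checks run at reduced scale chosen to
keep the physics unambiguous: sheet images 160 µm × 3 mm at 224 nm
transverse / 3 µm propagation sampling (the sheet varies slowly along
y); phantom stacks of order 10⁵–10⁶ voxels; 100-replicate fit-recovery
ensembles; 50-iteration deconvolutions on ~40×25×25 volumes.  Full
mesoscale frames (260 MP × 1000 planes) enter only through the
closed-form time and pixel-budget models, which are size-exact.

## Known limitations

- The effective NA behind a quoted 7.6 µm axial resolution is not
  derivable from the other published parameters; the formula value
  (6.45 µm) is reported as-is.
- Bootstrap uncertainties quantify row variability only.
- The ray-bundle shadow model re-mixes the beam instantly after each
  obstacle; real self-healing needs a finite reconstruction distance.
- The deconvolution PSF is Gaussian-separable; no vectorial or
  aberrated PSF generation.
- Stitching, visualization (CLAHE, 3-D rendering) and hardware control
  are out of scope.
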