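# Methods

This note documents the models behind `spectqc`: what the synthetic
generators emulate, how each analysis is defined, the numerical choices
made where the design was open, and what the tests do and do not show
about real scanner data.

## Scope and conventions

The package analyses the NU 1-2018 test battery as it applies to a
stationary ring of pixelated CZT detector columns (twelve columns of
seven stacked 16×16 modules, 2.46 mm pitch, 27.5 cm axial coverage).
Reconstruction is out of scope: SPECT volumes are *consumed* in
reconstructed space, and the simulator generates them there directly —
there is no system matrix, projector, or iterative algorithm.

All grids are right-handed, in millimetres, with the axial direction as
the third (Z) axis; voxel/pixel centres sit at `(index + 0.5)·spacing`
with 0-based indices. Every generator takes one explicit integer seed
per call (no global random state) and is bit-for-bit reproducible.

## The simulator

The generators reproduce the statistical structure the analyses rely
on, with known ground truth recorded alongside every output:

* **Spectra** — a Gaussian photopeak (σ = fraction·E_peak/2.3548) on a
  flat background over the 40–279 keV acquisition range, integrated per
  channel (0.5 or 1.0 keV) and Poisson sampled. The Compton continuum
  and CZT hole-tailing are *not* modelled; the NEMA estimator operates
  in a ±15 % window around the peak where the flat-background
  approximation is adequate.
* **Floods** — expected per-pixel counts proportional to a gain map,
  with defects injected as zero-gain (dead) or outlier-gain (hot)
  pixels.
* **Decay-source series** — the true input rate decays as
  `r₀·2^(−t/T_half)`; recorded counts integrate the detector's
  observed-rate response over each acquisition window (closed form for
  a lossless detector, adaptive quadrature at relative tolerance 1e-8
  otherwise), plus background.
* **Line / point / IEC volumes** — Gaussian-blurred sources integrated
  per pixel/voxel; the IEC phantom is a cylindrical approximation of
  the body phantom (wall radius 147 mm) with the six spheres on a
  57.2 mm coplanar ring, a 50 mm zero-count foam lung insert, optional
  Gaussian PSF, and Poisson noise. Scatter and attenuation are not
  modelled beyond the flat background term, so passing recovery tests
  validates the *analysis chain*, not the physics of a real
  acquisition.
* **Cylinder acquisitions** — per-detector summed images whose expected
  totals scale with per-detector sensitivity factors, for the volume
  sensitivity and detector-variation bookkeeping.

In noiseless mode the Poisson step is skipped, so any downstream
estimation error is attributable purely to discretization; the test
suite verifies that these errors shrink monotonically as channel/voxel
size is refined.

### The saturating count-rate response

The two headline count-rate readouts (a 760 kcps plateau and 20 % loss
at an input rate of 917 kcps) are not jointly consistent with a single
classical paralyzable or non-paralyzable dead-time model. The simulator
therefore provides a constructed readout surface,

    OCR(ICR) = min(ICR, ocr_max·(1 − e^(−ICR/k))),

with `k` solved so the 20 %-loss condition holds exactly at the stated
input rate. The clamp to the bisector keeps `OCR ≤ ICR` everywhere
(the raw exponential would overshoot the bisector at low rates for
plateau-matched parameters) and makes the detector exactly lossless at
low rate, which is what the extrapolation step of the analysis assumes
about its reference point. This validates the *readout procedure* — the
background correction, decay corrections, reference-point
extrapolation, and curve interpolation — not a dead-time physics model,
and no dead-time parameter fitting is attempted.

## Analysis definitions and numerical choices

* **Peak estimation** (shared by energy and spatial resolution): the
  parabola uses exactly the maximum sample and its two neighbours;
  plateau ties break to the lower index (flagged); a vertex outside the
  3-point support falls back to the raw maximum (flagged). The
  half/tenth-height threshold is taken from the parabola *vertex*
  ordinate, and the crossings are interpolated between the two samples
  bracketing the threshold nearest the peak on each side (robust to
  tail noise). On noiseless Gaussians the estimator's discretization
  error obeys `|error| ≤ h²/(2·FWHM)` (h = channel/pixel width); at
  0.5 keV channels and σ = 1 keV that is ~1.4 % of the width, and the
  tests assert this bound rather than an idealized continuum value.
  Profiles are analysed at native pitch — no upsampling — to keep the
  estimator simple and unbiased relative to the NEMA definition.
* **Energy-resolution window**: ±15 % around the nominal photopeak,
  wider than the clinical acquisition windows so the full peak shape is
  available. The width is a recorded default, not standard-prescribed.
* **Uniformity**: the UFOV of this pixelated column detector is the
  full binned grid (no Anger-style edge trimming); the CFOV is the
  central 75 % of each linear dimension rounded inward to whole
  super-pixels; the DU window is 5 super-pixels. Edge handling of the
  smoothing kernel renormalizes over in-bounds weights (a gather-style
  convolution), which leaves constant fields exactly unchanged — the
  property the uniformity statistic requires. Super-pixels at least
  half-filled with defective raw pixels are excluded from the
  statistics (configurable). Defect thresholds (0.7, 1.3 of the
  detector median) are recorded defaults; the manufacturer criterion is
  undisclosed.
* **Count rate**: the extrapolation reference is the latest measurement
  with OCR < 10 kcps (else the last point, flagged). The default
  schedule starts with a 10 s acquisition and grows durations by
  `2^(t/T_half)` (capped at 600 s) so expected counts per point stay
  constant. The 20 %-loss crossing is interpolated in log-ICR (the
  ratio is smoother there); multiple crossings resolve to the highest
  ICR; noise-inverted points (OCR > ICR) are kept in the curve but
  excluded from the crossing search.
* **SPECT views**: each source gets a slab of half-width 4× its coarse
  (moment-based) FWHM; radial/tangential directions follow the source's
  transverse position vector, sampled on the summed transverse view
  (exact grid lines when the layout is axis-aligned, bilinear profile
  sampling otherwise); the central source uses the grid axes.
  Triple-line widths are per-slice values averaged over the central
  80 % of the line extent.
* **Sensitivity**: the decay correction runs from calibration to
  acquisition *start*, with the `(1 − e^(−T_acq/τ))⁻¹` factor handling
  in-acquisition decay. The cylinder length for VSAC defaults to 20 cm
  and must be supplied for real data. Note the per-centimetre figure is
  defined as SVS/length; the unit string "kcps·MBq⁻¹·cm⁻²" occasionally
  quoted for it is dimensionally inconsistent with that definition, and
  the report says so.
* **Contrast ROIs**: membership is voxel-centre strictly inside the
  circle, single slice. Background templates sit at twelve 30°
  positions (offset 15° from the sphere ring) on a 108 mm ring, nudged
  radially outward in 2.5 mm steps before placement fails; every
  position must clear 15 mm margins to all spheres and the wall. Slice
  offsets snap to the nearest slice (±9.84, ±19.68 mm on the 2.46 mm
  grid). The lung summary is the mean over the five analysed slices;
  per-slice values are always emitted. The default IEC grid has an odd
  axial dimension so one slice lies exactly on the sphere plane and the
  noiseless full-recovery limit (Q = 100 %, N = 0) is exact.
* **Tc-99m constants**: half-life 21 625.2 s (mean lifetime
  τ = 31 198.6 s); effective septal length 17.72 mm.

## Problem sizes

The validation suite uses twelve 4.5 M-count spectra for the
energy-resolution fleet, a ~130-point decay-source series spanning
eleven half-lives, ~4×10⁷-count sensitivity acquisitions, 10⁶-count
cylinder images, and 128×128×49-voxel IEC volumes at 2.46 mm — matching
the study conditions while remaining desk-scale (the whole suite and
the acceptance script each run in a few seconds on one CPU).

## Known limitations

* No scatter, attenuation, collimator septal penetration, or
  reconstruction effects: contrast-recovery and resolution values on
  real data will differ from the synthetic full-recovery limits for
  physical reasons the simulator deliberately omits.
* The width estimator is biased high by `O(h²/FWHM)` when the source
  width approaches the sampling pitch; sources below twice the pitch
  violate the sampling-adequacy precondition and are flagged by the
  generator rather than silently analysed.
* DICOM support is minimal and tag-driven (spacing, counts, durations);
  vendor-specific private tags are not interpreted, and missing
  spacing information is a hard error rather than a guess.
* Daily-QC pass/fail limits are configuration with recorded defaults,
  not calibrated constants.
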