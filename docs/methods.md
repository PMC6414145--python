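# Methods

This note records the models implemented in `epidose`, the parameter
defaults and why they were chosen, the numerical decisions, and what the
synthetic simulator does and does not capture about measured portal images.

## Image formation and calibration

The detector signal behind an object of water-equivalent thickness
`t(x, y)` is modelled per pixel as

    I(x, y) = I0(x, y) · exp(−α(x, y)·t − β(x, y)·t²) · (1 + k0·A·t)

The exponential with a quadratic term is the attenuation model: `α`
(≈ 0.05 /cm at 6 MV) is the effective attenuation coefficient and `β`
(≈ 10⁻⁴ /cm²) absorbs beam hardening and off-axis spectral softening. The
trailing factor is a first-order scatter-to-primary ratio, SPR = k0·A·t,
proportional to the field area `A` (cm² at the isocentre plane) and the
object thickness; `k0 = 1.93×10⁻⁵ /cm³` encodes the system geometry and
phantom electron density.

Calibration fits `(α, β)` per pixel from flood images of uniform slabs at
t = {0, 2, 4, 7, 11, 16, 21} cm (the 0 cm image *is* `I0`), by unweighted
linear least squares on `−ln(I_t/I0) = α·t + β·t²`. Choices:

- **Log-domain, no intercept.** The model fixes I(0) = I0, so `I0` comes
  from the measured open field rather than the fit. The log transform makes
  the fit linear and closed-form; a nonlinear intensity-domain fit would
  weight thin slabs more heavily but changes recovered coefficients only at
  the noise level for this design. The fit is unweighted — nothing in the
  seven-point design justifies a particular weighting, and sensitivity to
  this choice is below the per-frame noise floor.
- **Scatter absorption.** The calibration slabs scatter too, so the fitted
  `α̂, β̂` absorb `−ln(1 + k0·A_calib·t)` in quadratic approximation. This
  is intentional: the reconstruction restores calibration-field scatter
  conditions before inverting, so the absorbed term cancels. Consequently
  exact (to 1e-8) parameter recovery is only observed on scatter-free
  series; with scatter included the *reconstruction*, not the coefficient
  values, is the accuracy target (≈ 0.004 cm RMS on the default phantom).
- **Validity flags.** Pixels with any non-positive slab or open-field
  signal, or non-positive fitted `α`, are flagged invalid and propagate to
  every downstream map rather than being silently used.

## Thickness reconstruction

Inversion uses the positive root

    t = [−α + √(α² − 4β·ln(I/I0))] / (2β)

the only branch giving t ≥ 0 when I ≤ I0 and β > 0. For |β| < 10⁻⁹ /cm²
the quadratic formula is numerically unstable and the exact exponential
limit `t = −ln(I/I0)/α` is used instead (the two branches agree to < 10⁻⁶ cm
at the threshold). Signals marginally above the open field (noise) clamp to
t = 0; non-positive signals and negative discriminants mark the pixel
invalid.

The treatment image differs from calibration conditions in field size and
scatter. Each correction cycle applies, to the **original** measured
intensity,

    I_corr = (I_meas / F) · (1 + k0·A_calib·t_i) / (1 + k0·A_treat·t_i)

with `F = I_open,treat / I_open,calib` per pixel (both open fields are
images, so F is a map; it also carries the wedge fluence), then re-inverts
to get `t_{i+1}`. Two readings of the printed recursion were rejected on
fixed-point grounds:

- Applying the ratio to the *previous iterate* compounds: the SPR ratio is
  not 1 at convergence, so the iterate diverges geometrically. Correcting
  the original image with the updated thickness estimate is the standard
  form of this algorithm and is contractive (each cycle shrinks the error
  by roughly `(c_ref − c_treat)/α ≈ 0.2`).
- *Multiplying* by F with F defined treat/calib double-counts the output
  factor: the measured treatment image already contains it. The default
  mode `normalize` divides; the literal orientation is kept available as
  `f_mode='paper_literal'` for comparison.

The first inversion of the uncorrected image is the "first estimate"
(iteration 0); `iterations_run` counts correction cycles. With tol =
0.01 cm the self-consistent synthetic breast case converges in 5 cycles
(final max|Δt| ≈ 0.009 cm); a fixed-iteration mode (`fixed_iters=5`) is
also provided. Non-convergence at `max_iter` returns the map with a warning
flag, never silently.

## Segmentation

The field mask thresholds at 0.5 × the robust maximum (99th percentile) —
the threshold fraction is a configurable assumption, as is the 8-connected
component rule; pixels exactly at threshold are included. The largest
connected component is kept and its boundary traced with a Moore-
neighbourhood walk emitting Freeman 8-direction codes; termination is by
state-cycle detection (pixel + backtrack direction), which remains correct
when the boundary passes through the start pixel twice.

The breast ROI is a polygon — supplied as vertices or projected from the
phantom outline — filled by an even-odd scanline with pixel-centre
inclusion; centres lying exactly on an edge are included, so a rectangle
with vertices on centres fills its full closed extent. Zero-area
(collinear) polygons yield a flagged degenerate fill; self-intersecting
polygons are rejected. In the pipeline, the ROI used for statistics is the
polygon fill intersected with the field mask and the validity mask.

## Dose comparison

Thickness maps convert back to relative intensity with fixed coefficients
α = 0.05 /cm, β = 10⁻⁴ /cm² (I0 = 1), giving a common dose surrogate for
static and moving deliveries. Two comparisons are made over the ROI, both
with **local** normalization:

- per-pixel relative differences `(D_mov − D_stat)/D_stat`, reported as the
  percentage of ROI pixels within 5/3/2/1%;
- a 2D gamma index with the dose criterion taken as a percentage of the
  reference dose at the compared position, at 5%/5 mm, 3%/3 mm, 2%/2 mm and
  1%/1 mm; pass rate = %(γ < 1).

Gamma numerics: the reference is sampled by bilinear interpolation on a
lattice `min(dist_crit, pixel_pitch)/interp_factor` (default factor 10, so
never coarser than a tenth of a pixel), within a search radius of
3 × dist_crit. Offsets are visited nearest-first and each ROI pixel drops
out of the search once its running γ² is below the pure distance term of
all remaining offsets, which makes the exhaustive lattice search cheap in
practice. No low-dose cutoff is applied inside the ROI — the ROI itself is
the restriction. The static (or day-one) image is always the reference and
the motion image the evaluated distribution. The test suite checks the
implementation against a brute-force fine-grid search with no radius
cutoff.

## The simulator

The simulator supplies every pipeline input and is first-class, tested
code. What it emulates, and the defaults (which are the study conditions
for all tests):

- **Phantom**: an analytic dome-on-ramp thickness function. The chest-wall
  ramp rises smoothly to 6 cm and saturates; an elliptical cos² dome
  (semi-axes 5 × 3.6 cm) centred in the field brings the apex to
  `separation_max` (default 16 cm, within the 0–21 cm calibrated range).
  The dome support is the "breast outline" used as auto-ROI. Geometry was
  chosen so the outline sits strictly inside the 14 × 8 cm field and the
  thickness gradient stays below 0.5 cm per 0.1 cm pixel. An analytic
  phantom permits exact oracles (truth thickness at every pixel).
- **Beams**: rectangular apertures with area `A`; 26 × 26 cm flat flood
  field for calibration, 14 × 8 cm treatment field whose wedge is a static
  multiplicative fluence ramp 0.5 → 1.0 along x. No MU-split wedge timing.
- **Motion**: 1D longitudinal (x) displacement. Sinusoids at 0.5/1.0/1.5 cm
  amplitude and 12–20 cycles/min; irregular patient-like traces drawn
  cycle-by-cycle from lognormal period/amplitude distributions (defaults:
  4 s mean period, CV 0.15; 1 cm mean amplitude, CV 0.2) with a sin⁴
  within-cycle shape (exhale plateau) and optional linear baseline drift —
  drift is an option, not an asserted property of real traces.
- **Acquisition**: 60 frames × 430 ms; the image is the frame mean of the
  transit image evaluated at each frame-midpoint displacement, plus a
  constant dark level (100 counts on I0 = 10⁴). Delivery starts at an
  arbitrary point of the breathing cycle (drawn from the seed unless given).
  Per-frame multiplicative Gaussian noise, default 0.5% — no noise model is
  prescribed by the physics here; 0.5% per frame leaves repeat static
  profiles within 1%, consistent with the reproducibility of measured
  systems.
- **Grid**: 256 × 256 pixels at 0.1 cm pitch (isocentre plane), a desk-scale
  stand-in for a 41 × 41 cm panel; configurable. x = columns, y = rows,
  pixel-centre coordinates, grid centred on the beam axis.

Every generator is a pure function of its arguments including the seed;
zero-amplitude "motion" is bit-identical to the static delivery.

What the simulator does **not** capture: Monte-Carlo transport, realistic
scatter kernels (scatter is exactly the first-order model the correction
removes, which is what makes forward/backward consistency testable but
means real residual-scatter errors are absent), detector glare/ghosting and
energy response, gain drift, 2D/3D motion, and deformation (the phantom
translates rigidly). Passing tests therefore demonstrate the correctness
and internal consistency of the algorithms and the qualitative motion
trends — amplitude sensitivity, frequency insensitivity, edge-band
blurring — not the exact pass-rate values a physical phantom would give;
measured tables differ quantitatively because real noise, scatter and
phantom geometry differ.

## Problem sizes used in checks

The packaged checks run the full 256 × 256 grid with 60-frame acquisitions
for the motion study and convergence checks; parameter-recovery repetitions
(10 seeds) use a 64 × 64 grid, and the gamma-oracle comparisons use 32 × 32
dose pairs, sizes at which the brute-force reference search is exact and
fast. These sizes are the package's reference configuration; all are
configurable.

## Known limitations

- The scatter correction is only as good as the first-order SPR model; k0
  is treated as known rather than fitted.
- The iterative loop assumes the open-field output-factor map F is noise-
  free enough to divide by; very low-signal pixels rely on the validity
  masks.
- Thickness above 21 cm extrapolates the calibration polynomial and is
  flagged, not prevented.
- Gamma pass rates at 256² are reported to the printed precision of the
  pass-rate tables; sub-0.1% differences between platforms can arise from
  BLAS summation order in the least-squares step.
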