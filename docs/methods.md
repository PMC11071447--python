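# Methods

## The measurement model

The assay quantifies antigen concentration through the capillary flow
rate of a sample wicking along a nitrocellulose channel preloaded with
antibody-conjugated particles. Horizontal imbibition in the porous strip
follows the Lucas–Washburn (L-W) law

    L(t) = sqrt(D t),    D = R * gamma_LG * cos(theta) / (2 mu),

where `L` is front distance (cm), `R` the effective capillary (pore)
radius, `gamma_LG` the liquid–gas interfacial tension, `theta` the
contact angle and `mu` the dynamic viscosity. Antigen-mediated particle
immunoagglutination perturbs the liquid properties at the wetting front
— predominantly `gamma_LG` — so the lumped diffusion coefficient `D` is
elevated in an early flow stage and relaxes to a lower constant value
once agglutination no longer influences the front. Flow profiles are
therefore modeled as two L-W regimes joined continuously at a crossover
frame `f_c`:

    L(t) = sqrt(D_early * t)                               t <= t_c
    L(t) = sqrt(D_early * t_c + D_late * (t - t_c))        t >  t_c

The assay signal is the flow distance at a fixed detection frame inside
the early regime.

## Front tracking

The detector samples intensity on the 1-pixel central axis of each
channel ROI (median over a 3-pixel transverse band), subtracts the
pre-flow baseline frame, and takes the front as the farthest along-axis
pixel whose absolute change exceeds `threshold_rel` (default 0.5) of the
maximum wetted change in that channel. Profiles are monotone-enforced
(running maximum — capillary fronts cannot recede) and capped at the
channel length. On noiseless rendered stacks the recovered profile is
threshold-independent over `threshold_rel` in [0.2, 0.8] and within one
pixel of the generating profile, which is the module's primary contract.
Channel ROIs come from configuration, not auto-detection: chips sit in a
fixed holder, so geometry is constant. A channel with no intensity
change anywhere is reported as all-zeros with a `dry` flag.

Frame 0 of a profile is the tracking baseline frame (first frame after
sample loading); distances are measured from the loading-zone exit. The
frame-rate convention is 30 fps (1,500 frames = 50 s), stored in
configuration and never hard-coded.

## Diffusion-coefficient estimation

Two estimators are provided. The pointwise series `D_i = L_i^2 / t_i`
(t = 0 excluded) is smoothed by a moving average of width 10 frames,
centered with shrinking windows at the boundaries — a centered window
avoids the phase lag a trailing average would add to the crossover
estimate. Window fits minimize squared residuals of `L = sqrt(D t)` on
`L`; because the model is linear in `sqrt(D)` the fit has the closed
form `sqrt(D) = sum(L sqrt(t)) / sum(t)`. A linearized alternative
(regressing `L^2` on `t` through the origin) is offered and agrees
within 1% on noiseless data. Smoothing is applied per channel and series
are averaged across channels afterwards.

## Detection-frame selection ("halfway")

Past the kink, the pointwise series decays hyperbolically:

    D(f) = D_late + (D_early - D_late) * f_c / f,

so it reaches the midpoint of the early and late levels only at `2 f_c`
— a midpoint-threshold crossing alone would double-count the crossover.
Instead the estimator uses the equivalent linear form: `f * D(f)` is
linear in `f` after the kink with slope `D_late` and intercept
`(D_early - D_late) * f_c`. The early level is the maximum of the
smoothed pooled series over frames 1–15; post-kink frames are those with
`D < 0.85 * early` whose mean front is still advancing (saturation at
the channel end bends `f*D` downward and is excluded); an OLS line over
them gives `f_c = intercept / (D_early - slope)`. The selected detection
frame is `round(f_c / 2)` — the halfway point of the initial steep
stage, where concentration discrimination is largest. With a crossover
at frame 50 this returns frame 25 (~1 s at 30 fps). A flat series (no
early/late contrast above 5%) returns the configured default frame with
a warning. The `max_separation` alternative returns the frame maximizing
the one-way between/within variance ratio of distance across
concentration groups.

## Immunoagglutination kinetics

Five species evolve by mass action in dimensionless model units
(the simulation reproduces trends, not absolute molarities):

    Abp + Ag      <=> Abp.Ag     kon1 = 6,  koff1 = 0.1
    Abp + Abp.Ag  <=> Abp2.Ag    kon2 = 1,  koff2 = 0.05
    Ag  + Abp.Ag   -> Abp.Ag2    kon3 = 2   (dissociation neglected)

`Abp2.Ag` — two particles bridged by one antigen — is the agglutination
readout. `Abp.Ag2` captures antigen consumption without particle
aggregation; its production-only rate `kon3*[Abp.Ag]*[Ag]` is required
to close both conservation laws (particles: `Abp + Abp.Ag + 2 Abp2.Ag +
Abp.Ag2`; antigen: `Ag + Abp.Ag + Abp2.Ag + 2 Abp.Ag2`), which are the
integrator's acceptance check (relative drift < 1e-6; observed ~1e-14).
Integration is adaptive Runge–Kutta (RK45, rtol 1e-8 / atol 1e-10);
negative excursions beyond 1e-8 raise, smaller ones are clamped to zero
rather than projected. Dose curves sample `Abp2.Ag / Abp0` at `t = 1`,
where binding has leveled off for the default constants; they rise with
antigen, plateau, and fall in the antigen-excess (hook/prozone) zone,
and halving `Abp0` shifts the curve left so the two curves cross —
the mechanism behind "flipped" trends at reduced particle load.

## Calibration statistics

The negative control is the 0-concentration group. The LOD is the lowest
concentration whose replicates differ from control by a Welch
(unequal-variance) t-test at raw two-sided P < 0.05 — deliberately
uncorrected for multiple testing, matching immunoassay practice; the
per-comparison false-positive rate this implies (~alpha per tested
concentration) is characterized in the test suite. The calibration model
is a 4-parameter logistic on log10 concentration, with the control
placed one decade below the smallest nonzero concentration; when the
mean response shows an interior maximum and at least five pre-peak
points remain, the post-peak hook limb is excluded from the fit and
recorded. Non-convergent or flat fits fall back to a linear fit with a
flag. The linear range is formalized as the widest contiguous window of
at least 3 concentrations whose OLS fit of mean signal on concentration
reaches R² ≥ 0.75 (ties broken by higher R²); the published ranges state
no rule, so this criterion is this package's own. Tier classification
inverts the calibration (closed form for the 4PL) and bins at two
concentration cuts, a signal exactly on a cut going to the higher tier;
decreasing calibrations invert correctly without special casing.
Dilution conversion divides (to undiluted) or multiplies (to diluted) by
the volume fraction; following the field's reporting convention,
undiluted equivalents print in ng/mL once ≥ 0.1 ng/mL and diluted values
in pg/mL below 1000 pg/mL.

## Synthetic data: what it emulates and what it does not

`SynthConfig` defaults are chosen to be physically self-consistent in
CGS units: water-like viscosity (0.01 P), interfacial tension mapped
linearly from normalized agglutination onto 40–72 dyn/cm (72 = clean
water), effective pore radius 2.8 µm and contact angle 0°, giving
`D_early` ≈ 0.56–1.0 cm²/s; `D_late` = 0.08 cm²/s fills the 2.1 cm
channel in roughly 1,300 frames at 30 fps, the time scale real chips
show. The crossover defaults to frame 50 and the detection frame to 25.
Concentrations in pg/mL are scaled by 0.1 into model antigen units so
the hook peak of the default rate constants falls near 50 pg/mL, at the
top of the assay's working range. The linear agglutination→tension map
is the minimal monotone assumption: the direction and dominance of the
interfacial-tension effect are established by measurement, but no
functional form is, and none of the package's inferences depend on the
map beyond monotonicity. Distance noise is i.i.d. Gaussian per frame
(default sd 0.01 cm; only standard errors, not noise spectra, are
reported for the real assay, so the magnitude is a free parameter).
Videos are flat-background luminance stacks with a sharp darkened wetted
region — sufficient for the tracking contract, not photorealistic.

Consequently, passing tests demonstrate correctness of the algorithms
under the assumed structure (two-regime L-W flow, monotone
agglutination→tension link, Gaussian replicate noise); they do not
certify performance on real videos with illumination drift, chip pose
variation, blood-matrix optics, or spatially uneven particle retention.

## Numerical and design choices

- Fit windows are inclusive frame ranges; the t = 0 sample is excluded
  from every D computation.
- `fit_lw` closed forms make noiseless recovery exact to machine
  precision; R² is reported against the mean-only model.
- Hook-peak location uses the grid argmax with ties toward lower
  antigen; crossing location interpolates linearly between bracketing
  grid points.
- Degenerate inputs are contracts, not crashes: dry channels flag
  `dry`, all-zero fit windows raise `DegenerateFitError`, missing
  negative controls raise, zero-variance Welch comparisons return
  p ∈ {0, 1} explicitly, monotone dose curves return a boundary-peak
  flag.
- Problem sizes in the test suite and acceptance script (300–1,000-frame
  profiles, 40-point dose grids, 50–100 random kinetic parameter sets,
  200/1,000 Monte-Carlo repetitions) were chosen as the smallest sizes
  at which the measured quantities are stable to well inside their
  tolerances.

## Known limitations

- Aggregates larger than two particles, spatial reaction–diffusion in
  the paper matrix, and stochastic (Gillespie) kinetics are out of
  scope.
- Vertical/gravity-corrected imbibition and evaporation corrections are
  not modeled.
- The kinetic model's antigen axis is dimensionless; mapping to molar
  units would require binding constants the assay does not measure.
- ROI auto-detection is deliberately absent; geometry comes from the
  chip holder configuration.
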