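# Methods

## Normative model

Each ROI group's FA observations are modelled with a one-way random-intercept
linear mixed model: `y_ij = μ + b_i + ε_ij`, with subject effect
`b_i ~ N(0, τ²)` and residual `ε_ij ~ N(0, σ²)`. Repeated ROIs within a
subject (e.g. genu and splenium circular ROIs, both tagged `CC_CROI`) are the
repeated observations; pooling them reflects that LUT anchors stand for
*fiber-density strata*, not single structures.

Two estimators are exposed:

- **`reml`** (default): restricted maximum likelihood via statsmodels
  `MixedLM`. Because generic optimizers can stall on variance-component
  boundaries, the fit is verified against the closed-form restricted
  log-likelihood of the one-way model (Woodbury form of
  `V_i = σ²I + τ²J`); if the one-way ANOVA solution attains a higher
  restricted likelihood, it is taken instead, and the fixed effect is always
  re-estimated by GLS at the selected variance components. On balanced
  designs with `τ̂² > 0` the two solutions coincide analytically, which the
  test suite checks to 1e-6.
- **`moments`**: the classical one-way ANOVA estimators — `σ̂²` is the
  within-subject mean square and `τ̂² = max(0, (MSB − MSE)/k̃)` with
  `k̃ = (N − Σn_i²/N)/(m − 1)` handling unbalanced subject counts. Negative
  estimates truncate to zero, keeping the prediction interval well-defined.

Constant data (zero spread) short-circuits to the exact degenerate fit
`(μ̂ = y, τ̂² = σ̂² = 0)` without invoking an optimizer.

### Prediction interval

The 95% interval for a *new observation from a new subject* is
`μ̂ ± z₀.₉₇₅·√(τ̂² + σ̂²)` with the normal quantile `z₀.₉₇₅ = 1.959964`.
Fixed-effect estimation uncertainty is excluded by default: at 76 subjects
its contribution is negligible relative to the printed interval widths, and
the published intervals are reproduced without it. A flag
(`include_mean_uncertainty`) adds `Var(μ̂) ≈ (τ̂² + σ̂²/k)/m` for users with
small cohorts who want the conservative interval. A t quantile is not used
for the same reason (n = 76 makes the correction invisible at printed
precision). Bounds are deliberately not clipped to [0, 1]; clipping is the
LUT builder's concern, so the model output remains symmetric and invertible.

Age enters many FA references as a covariate; the default fit omits it
because the normative anchor values are reproducible without one, and the
functional form of any site's age correction is a site decision. The model
surface accepts only the intercept; sites needing an age term should adjust
FA upstream.

## Synthetic cohort generator

The generator draws from exactly the fitted model, per group: total variance
recovered from the published PI width, `τ² + σ² = ((PI_hi − PI_lo)/(2z))²`,
split by `icc_fraction` (default 0.5 — only PI widths are published, not the
between/within variance split, so an equal split is assumed and is
configurable per group). Values are clipped to [0, 1] after noise: FA is
mathematically bounded, and at the normative parameters the clipping
probability is below 0.4% in the most extreme group (MCP upper tail), with
bias far below the acceptance tolerances. Record counts are exact —
`Σ n_subjects × rois_per_subject` — because clipping never drops records.

The default scheme mirrors the normative cohort: 76 subjects × 16 ROIs
(BG 6: bilateral putamen/pallidum/caudate; GM 4: bilateral precentral gyrus
and thalamus; CC freehand 2; CC circular 4) = 1216 records. Bilaterality of
the gray-matter ROIs is an assumption (only the totals are published) and the
partition is fully configurable through `GroupSpec`.

Pooled specifications ship for two validation structures measured with the
same methodology: pyramidal tract (combined circular + freehand, FA 0.75,
PI 0.67–0.82) and middle cerebellar peduncle (FA 0.73, PI 0.54–0.93).

**What the generator does not emulate:** spatial structure of measurement
error, age dependence of FA, inter-rater ROI placement variability,
non-Gaussian tails from tensor-fit failures, and scanner drift. Passing
recovery tests therefore demonstrates the *statistical pipeline* is correct
and unbiased under the stated model, not that a given scanner's cohort
matches the published values.

## Phantom

A geometric stand-in for an FA map, synthetic by construction: nested
ellipsoids (gray-matter shell at FA 0.323, deep white-matter core at 0.709)
with two spherical "peduncle" blobs at FA 0.82 (the MCP circular-ROI mean)
inside a zero-FA background, plus optional voxelwise Gaussian noise
(default SD 0.02, clipped to [0, 1]) and an `msa_delta` FA decrement applied
to the peduncles before noise. It supports order-of-color checks (a diseased
phantom's peduncles must lose red intensity) — it has no anatomical validity
beyond that. Volumes are written as NIfTI-1 with 2.2 mm isotropic voxels,
matching the acquisition resolution of the normative data.

## LUT construction

Anchors, in FA order: `0, BG.PI_lo/2, BG.PI_lo, BG.μ, GM.μ, GM.PI_hi,
CCf.PI_lo, CCf.PI_hi, CCr.μ, 1`. Anchor FA values are clipped into [0, 1]
and must then be *strictly* increasing; a violation (possible only with a
pathological cohort) raises an error naming the offending pair rather than
silently reordering.

Colors ramp linearly per RGB channel between consecutive anchors, computed in
continuous space and rounded half-up — interpolate-then-round, never
round-then-interpolate, so the maximum channel discontinuity due to rounding
is 1. FA outside [0, 1] clamps to the endpoint colors (excursions are
numerical noise from tensor fitting). FA exactly at an anchor returns the
anchor color exactly.

The original anchor colors survive only as CMYK print and cannot be
recovered as RGB values, so the shipped default palette is a design choice, not a
reproduction: deep gray renders in blues, cortical gray in greens, and dense
white matter red → yellow with rising FA, preserving the qualitative reading
(healthy peduncles red/yellow; diseased ones visibly darker/greener). The
palette lives in an editable YAML file (`falut/data/palette_default.yaml`)
with endpoints black (FA 0) and white (FA 1). Injectivity of the 256-entry
discretization (every FA bin a unique color) holds for this default palette
and is tested; arbitrary user palettes need not be injective.

Exports: raw ImageJ `.lut` (exactly 768 bytes: 256 red, 256 green, 256 blue,
sampled on the closed grid k/255) and a CSV colormap (`index,fa,r,g,b`) that
round-trips bit-exactly and serves as the interchange format for the
colorizer CLI.

## Colorizer and display

Colorization is a pure per-voxel map: finite in-mask voxels go through the
anchor polyline; NaN and out-of-mask voxels render exact black. Note the
consequence: tissue at FA ≈ 0 is distinguishable from background only if the
FA-0 anchor color is configured away from black. On load, values below 0 /
above 1 clamp (counted and logged) and non-finite voxels become background.

Mosaics use nearest-voxel slicing only — no resampling or smoothing, which
would blur FA through partial-volume mixing. Display is radiological by
default (subject's left on image right) with a `--neurological` flag. A
horizontal color-bar strip of the LUT is appended below the slice grid. PNG
output is deterministic for fixed inputs.

## Agreement and screening statistics

- **Scheme agreement** (12 vs 30 encoding directions): Bland–Altman on paired
  differences `d = fa_12 − fa_30`; the 95% interval for a new difference is
  `mean(d) ± z·sd(d)` (sample SD, n−1), plus Pearson r with a two-sided
  p-value. A constant side raises an explicit error instead of fabricating a
  correlation.
- **Screening**: MSA is the positive class; sensitivity = 100·TP/(TP+FN),
  specificity = 100·TN/(TN+FP). Exact rationals are retained; reported values
  round half-up to integer percent, matching the convention of the published
  rater table. Rater averages are means of the per-rater *printed-precision*
  percentages (e.g. (77+100+76+65)/4 = 79.5 → 80); averaging exact fractions
  would differ, and per-rater raw counts are not published, so the
  printed-precision convention is the only reproducible one.

## Problem sizes and numerical choices

- Recovery experiments: 50 replicates × 76 subjects per group, chosen to pin
  the replicate-averaged mean to ≈ ±0.001 (Monte-Carlo SE) against tolerances
  of ±0.005.
- Large-sample generator checks: 5 000 subjects, tolerance ±0.01 on mean and
  2.5/97.5 percentiles.
- REML/ANOVA equivalence tolerance: 1e-6 on balanced designs off the
  variance boundary.
- All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical tables, phantoms, and exports.

## Known limitations

- The default palette is provisional (see above); quantitative color values
  are site-configurable, only the anchor *positions* are normative.
- Interpolation is in RGB, not a perceptually uniform space; equal FA steps
  are not guaranteed equal perceptual steps.
- The human-rater screening study cannot be reproduced computationally; only
  its summary arithmetic (averaging the published per-rater percentages) is
  computed here.
- Prediction intervals assume Gaussian subject effects and residuals; heavy
  tails in a real cohort would widen true intervals relative to the model.
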