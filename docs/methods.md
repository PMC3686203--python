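# Methods

This note records the models implemented in `deforecast`, the choices
made where the underlying methodology leaves room, and what the
synthetic-data tests do and do not demonstrate.

## Demographic model

Census counts per administrative unit follow
P_k(t) = (α₀ + b_k)·e^{ρt} + ε with ε ~ N(0, V) and b_k ~ N(0, V_b);
t is measured in decimal years from 1993 (t = 0), the year of the
older town-level census. Priors are the standard noninformative
conjugates: Normal(0, 10⁶) for α₀ and ρ, Inverse-Gamma(0.001, 0.001)
for V and V_b.

*Error scale.* The Gaussian error is additive on the population scale,
not the log scale. This makes the model linear in (α₀, b_k) given ρ,
so everything except ρ has a conjugate Gibbs update and only ρ needs a
Metropolis step. A log-scale error (multiplicative noise) would be an
equally defensible choice; it would change the weighting of large
versus small units but not the structure of the sampler.

*Linking two censuses at different levels.* The older census counts
towns (firaisana); the newer one counts sub-towns (fokontany) that
nest inside them. Sub-town records are aggregated upward — populations
summed per parent town and date — so both censuses inform a single
per-town trajectory. Aggregation is exact for counts; the alternative
(downscaling town counts to sub-towns) would require an arbitrary
spatial disaggregation rule.

*Sampler.* Gibbs for α₀, b_k (unit by unit), V and V_b; Gaussian
random-walk Metropolis for ρ with the proposal scale adapted during
burn-in toward a 20–50% acceptance band. Defaults: 5,000 burn-in
+ 5,000 sampling iterations, thinned by 5 (1,000 retained draws),
fixed user seed. Chains start from moment estimates — the median
per-unit log-ratio growth rate, the implied 1993 intercept, and the
residual variance at that start — rather than from zero. This matters:
the joint (ρ, V) posterior is a funnel, and a cold-started chain can
drift into a diffuse high-V region where the likelihood is nearly
flat.

*Known degeneracy.* With very few observations (e.g., a single unit
observed twice) the posterior under these vague priors genuinely
places non-negligible mass on the "no signal, large variance" region:
the model is then effectively unidentified and chains may visit that
region no matter how they are initialized. This is a property of the
model at n = 2, not of the sampler; growth-rate recovery should be
expected only with several units and/or dates (the test suite uses 50
units at two dates, and a single unit at four dates for the noise-free
closed-form check).

## Interval-corrected deforestation models

Both the intensity and the location model are Bernoulli logistic
regressions on the *annual* clearing probability θ, observed through
per-pixel intervals Y (years): z ~ Bernoulli(θ′), θ′ = 1 − (1 − θ)^Y,
logit(θ) = xᵀβ. Satellite mosaics give neighbouring pixels different
acquisition dates, so Y varies within one landscape by a year or more;
the exponent converts all observations to a common annual scale.
With Y ≡ 1 the likelihood reduces exactly to standard logistic
regression (verified against an independent GLM solver).

- Intensity: x = [1, D], D the unit-level population density in
  peop·km⁻². Fitted on pixels sampled at both historical change
  periods (the earlier period contributes rate information even though
  it lacks the distance-to-previous-clearing covariate).
- Location: x = spatial covariates in raw units (m, peop·km⁻²),
  with the fragmentation class treatment-coded against the "patch"
  reference level. No internal standardization: reported coefficients
  stay in interpretable per-meter / per-density units.

*Sampler.* Componentwise Gaussian random-walk Metropolis, proposal
scales adapted during burn-in (same 20–50% band), flat Normal(0, 10⁶)
priors; defaults 5,000 + 5,000 thinned by 5. The intercept starts at
the logit of the annualized overall event rate, slopes at zero, which
places the chain inside the posterior basin even at ~1% event rates.
The log-likelihood uses log(1 − θ′) = −Y·log(1 + e^η) and clamps
probabilities to [10⁻¹², 1 − 10⁻¹²]; a possible complete separation is
reported as a warning when the coefficient posterior diverges.

*Sample size.* The normal approximation to the binomial confidence
interval gives n = ⌈z²p(1−p)/h²⌉ observations to estimate a rate p
within ±h. At p = 1%/yr and h = 0.1%/yr this is 38,031 with the exact
97.5% quantile (z = 1.95996) — ~38,000 at two significant figures,
which motivates the default of 20,000 sampled pixels per change
period.

*Model selection.* Variable importance (deviance of the reduced model
minus deviance of the full model, at posterior-mean coefficients) and
95% credible intervals are reported; the final covariate choice is
left to the user. An automatic selector is deliberately not provided:
a defensible final model must also reject statistically significant
but process-inconsistent effects (e.g., an apparent *higher* clearing
probability inside protected areas caused by confounded landscape
covariates).

## Landscape covariates

- *Distances* are center-to-center Euclidean (meters), computed with
  an exact Euclidean distance transform and cross-checked against an
  O(N²) brute-force oracle. "Distance to forest edge" is defined for
  forest pixels only (distance to the nearest non-forest pixel);
  non-forest pixels carry nodata.
- *Fragmentation* follows the Riitters moving-window scheme: Pf is
  the forest proportion in the window, Pff the forest–forest share of
  cardinal-adjacent pixel pairs with at least one forest member.
  Thresholds: interior Pf = 1; patch Pf < 0.4; transitional
  0.4 ≤ Pf < 0.6; perforated Pf ≥ 0.6 and Pf > Pff; edge otherwise.
  The window defaults to 7×7 (210 m at 30 m pixels) — a common choice
  at Landsat resolution — and is configurable because the appropriate
  scale is study-specific. Windows are cropped at raster borders
  (statistics over available cells), which avoids inventing
  out-of-map forest.
- *Pixel sampling* excludes pixels under cloud or shade at either
  endpoint of a change period; each sample carries the decimal-year
  interval of its mosaic piece.

## Forecast simulator

Annual time step from s₀+1 to the horizon. Per year: project unit
populations at the posterior-mean ρ, build the density map, average
density over *still-forested project-site pixels* (the density the
remaining forest actually experiences), convert to θ₀ through the
intensity model at posterior-mean coefficients, and clear the
n₁ = ⌊θ₀F + carry⌋ highest-transition-potential pixels.

- *Posterior means, not draws.* Forecasts use a single fitted model;
  propagating full posteriors would give uncertainty envelopes but is
  out of scope here.
- *Fractional allocation.* θ₀F is rarely an integer; the fractional
  remainder is carried to the next year instead of being rounded away,
  so no systematic ~0.5 pixel/yr bias accumulates over a 20-year
  horizon.
- *Ties.* Pixels with exactly equal transition potential are ordered
  by a seeded uniform draw: float-equal ranking would otherwise be
  platform-dependent and runs would not be bit-reproducible.
- *Dynamics.* Distance to forest edge, distance to previously cleared
  patches and the fragmentation class are recomputed from the current
  forest state each year (only those the location model actually
  uses); every other covariate is frozen at its s₀ value, including
  per-pixel density within a year.
- Degenerate cases: horizon = s₀ returns an empty series; exhausting
  the forest stops the run early with a warning; n₁ is capped at the
  available forest.

## Carbon accounting

Aboveground carbon density (ACD, Mg C/ha) maps are prepared in two
steps: forest pixels with missing ACD (cloud/shadow in the source
imagery) take the mean valid-forest ACD of their project site, then a
3×3 moving average suppresses salt-and-pepper noise. Filling precedes
smoothing so that gap values cannot leak zeros into their neighbours'
averages; windows crop at borders and nodata. The ACD map is frozen
over the forecast horizon. Emissions per pixel are
ACD × 0.09 ha × 44/12 Mg CO₂ (30 m pixel; molecular-to-atomic mass
ratio of CO₂ to C). Belowground biomass and soil carbon are excluded.

## Validation

Repeated (default 10×) 70/30 random splits of the later change
period's samples. Per repeat the intensity model is refit on the
training split pooled with the earlier-period samples, the location
model on the training split alone. Continuous transition potentials
are binarized by *expected-count ranking*: the intensity model's
interval-corrected probabilities are summed over the test rows to an
expected cleared count, and that many highest-potential rows are
predicted cleared. This mirrors the simulator's allocation rule; a
0.5-probability threshold would predict no clearing at ~1% prevalence
and make every index degenerate. Indices: OA, FOM, Sen, Spe,
TSS = Sen + Spe − 1, and Cohen's κ, reported ×100 as mean (sd) over
repeats. Undefined ratios (zero denominators) are reported as NaN,
never as 0.

## Synthetic data

`synthgen` emulates the structure of the real inputs at desk scale:

- spatially autocorrelated forest masks (thresholded smoothed Gaussian
  noise; the correlation length tunes fragmentation, and the forest
  fraction is imposed exactly by quantile thresholding inside a
  40–60% band);
- Voronoi administrative units partitioning the grid;
- censuses drawn from the demographic model itself (defaults:
  ρ = 0.0339 yr⁻¹, α₀ = 10,000, 50 units, observed 1993 and 2006);
- three-date land-cover series with vertical mosaic slabs carrying
  different acquisition dates (intervals of ~3.7–5.5 yr), cleared by
  per-pixel Bernoulli draws at the interval-corrected annual
  probability expit(β₀ + β₁D), optionally modulated by a normalized
  location weight expit(xᵀγ) and optionally overwritten by cloud
  patches;
- direct tabular samples from the intensity model
  (D ~ U(0, 100), Y ~ U(4, 6)) for recovery experiments at chosen n.

With γ = 0 the generator *is* the intensity model's data-generating
process, so recovery tests are exact calibration checks. With γ ≠ 0
the multiplicative modulation is an approximation: it preserves the
landscape-mean rate but is not the top-n₁ allocation the simulator
applies, and per-year covariate dynamics within an observation
interval are evaluated at the interval start. What passing tests show
is therefore that the estimators recover the parameters of their own
assumed process and that the simulator obeys its contracts — not that
the logistic form, the uniform-density-within-unit assumption, or the
frozen-covariate assumption hold on real landscapes.

Default problem sizes (200×200 grids for full-landscape runs, 40,000
samples for recovery, 20 replicate fits) keep the complete suite in
the minutes range on a single core while leaving binomial standard
errors small enough for the stated tolerances.

## Reproducible published quantities

The acceptance script re-evaluates, through the package's own
routines, the numbers that are reproducible from published inputs
alone: the per-site predicted annual deforestation rates
100·expit(β₀ + β₁D̄) at the published coefficients and projected mean
densities, the 38,000-observation sampling bound, and the per-hectare
emission rate implied by the published cumulative totals
(18,201,512 Mg CO₂ / 407,000 ha / 20 yr). Three published
rate cells (Fandriana 2010/2030, Ivohibe 2010, Fort-Dauphin I 2030)
do not reproduce at two decimals from the *rounded* published
coefficients (e.g., Fandriana evaluates to 2.90 vs the published 2.94)
— the originals were evidently computed from unrounded posterior
means — and are therefore documented here rather than asserted.

## Limitations

- No spatial autocorrelation term in the location model; residual
  clustering of clearing beyond the included covariates is not
  captured.
- One growth rate ρ is shared across all units; demographic
  heterogeneity enters only through the 1993 intercepts.
- The simulator does not model road growth, policy scenarios, or
  feedback of deforestation on population.
- Equal-area metric grids are assumed throughout; no reprojection or
  resampling is provided, and misaligned rasters are rejected rather
  than resampled.
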