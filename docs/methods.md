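# Methods

This note documents the models implemented in `spectraits`, the synthetic
field trial that stands in for field data, the numerical choices made, and
what the tests do and do not demonstrate.

## The regression core

`plsr_core.fit_pls1` implements single-response partial least squares with
the orthogonal-scores (NIPALS) iteration.  X and y are mean-centered only;
no unit-variance scaling is applied by default because reflectance bands
share units and centering-only is the conventional default of the
orthogonal-scores method (an autoscaling flag would be a one-line wrapper
around the same core).  Component extraction stops early when the residual
covariance ‖Xᵀy‖ falls below 1e-12 of its initial value, which prevents
numerically empty components on degenerate data; a constant response
yields a valid zero-component model (B = 0, intercept = ȳ) with a warning
rather than an error, because downstream code can still predict with it.
Coefficients are recovered as B = W(PᵀW)⁻¹q; PᵀW is unit upper triangular
in exact arithmetic, and a condition number above 1e12 raises with advice
to use fewer components.  At full rank B coincides with the least-squares
solution, which the tests exploit as a closed-form oracle.

Predictions are never clipped to physically admissible ranges: validation
metrics must be computed on raw predictions, and clipping would silently
bias them.  Flagging impossible values (negative conductance) is left to
the caller.

## Model assessment

Cross-validation refits the model for every held-out unit and accumulates
PRESS over component counts; RMSEP = √(PRESS/n).  Leave-one-out is the
reference scheme (and the one the brute-force oracle checks); k-fold
(k = 10) is the pipeline default on trial-sized data, where LOO would refit
hundreds of models per trait for no change in the selected component
count in practice.  Selection takes the argmin of RMSEP with exact ties
broken toward fewer components; under LOO the RMSEP and PRESS minima
coincide by construction, so "smallest RMSEP in conjunction with smallest
PRESS" is one rule, not two.

The jackknife is implemented as delete-one resampling: exhaustive whenever
the requested iteration count reaches n (and therefore seed-independent),
otherwise a seeded subset of delete-one fits, with the variance rescaled
by n/m to stay consistent.  The classical identity — jackknife variance of
the sample mean equals s²/n — is used as an exact test through the p = 0
degenerate path, where the "model" reduces to the mean.

R² is reported as the squared Pearson correlation between observations and
predictions, the convention in the leaf-spectroscopy literature where
figures regress predictions on ground truth; 1 − SSE/SST is carried in the
same report (`r2_ss`) for readers who prefer the skill-score definition.
Bias is reported both in trait units and as a percentage of the observed
mean, because the two are easy to conflate when traits span four orders of
magnitude.

VIP scores use SSYₐ = qₐ²tₐᵀtₐ as the response variance captured per
component; the Σⱼ VIPⱼ² = p identity is asserted to 1e-6 on every fitted
model.  Important regions are maximal contiguous runs with VIP strictly
above the threshold (default 1), reported as closed nm intervals; a
`min_width` filter drops single-band spikes when asked.

## Trait arithmetic

Aboveground biomass is TotalFW × (SubsampleDW/SubsampleFW) / HarvestedArea
in g m⁻², i.e. the fresh harvest scaled by the oven-dry fraction of a
50-shoot subsample per harvested area — the only dimensionally consistent
reading of the field protocol.  LAI is green lamina area per stem × stems
per m² (dimensionless); SLA = area/mass (m² kg⁻¹) and LMA its reciprocal
(kg m⁻²), units chosen so typical wheat values are ~20 and ~0.05.  Canopy
photosynthesis weights each layer's A_sat by that layer's LAI and sums
over exactly three layers — a missing layer is an error, never a silent
two-layer fallback.  Pooled g_s is the unweighted three-layer mean; an
LAI-weighted variant exists but is off by default because the pooled value
is defined as a plain average of the canopy positions.

## RUE and genotype BLUEs

Intercepted PAR accumulates daily irradiance × 0.45 (PAR fraction of
global radiation) × fAPAR, with fAPAR linearly interpolated in time
between ceptometer readings and held constant beyond the last one;
a window with no reading at or before its end is an error rather than an
extrapolation.  RUE is the OLS slope of biomass on accumulated intercepted
PAR over a growth interval; supported intervals are E40–InB, InB–A7,
grain filling (A7–PM) and Total.

BLUEs come from the multi-environment linear mixed model with genotype
fixed (parameterized cell-means style, so each coefficient *is* the
genotype's adjusted mean), an optional phenology covariate fixed and
centered (adjusted means are therefore at the covariate mean), and
environment, replicate-within-environment and environment × genotype
random, fit by REML through statsmodels.  The covariate is included by
default with a switch to drop it, since the inclusion criterion in field
practice varies.  Single-environment data degrades to fixed genotype +
covariate with replicate random.  Degenerate fits — non-convergence,
non-finite estimates, or a residual variance at numerical zero, where the
REML surface is flat and the fixed effects can absorb an arbitrary shift —
fall back to the OLS projection, which in the balanced zero-variance case
reproduces raw genotype means exactly.

## The synthetic field trial

The generator emulates an irrigated spring-wheat trial: 11 genotypes,
3 replicates, 3 one-year environments, two growth stages (initiation of
booting, 7 days after anthesis) and three canopy layers, one spectrum and
one full trait record per combination (594 samples).  Layer × stage trait
targets (means and SDs) are fixed at values typical of such canopies —
e.g. A_sat falling from 22 to 10 μmol m⁻² s⁻¹ from flag to third leaf
during grain filling, while at booting the middle layer slightly exceeds
the top — so the layer and stage structure the combined-vs-per-layer
comparison relies on is present by construction.

Each sample has a latent leaf state (chlorophyll, nitrogen, water, dry
matter).  Reflectance is a smooth downward-sloping continuum minus
latent-scaled Gaussian absorption features: chlorophyll at 430/460/670 nm
plus a red-edge shoulder near 700–750 nm, water at 1450/1940 nm,
nitrogen and dry matter in the 2050–2200 nm window, plus i.i.d. band noise
(default SD 0.002 reflectance units, the regime of a well-calibrated leaf
clip).  This is a minimal Beer–Lambert-flavored construction — deliberately
not a radiative-transfer model (no PROSPECT-class physics, no BRDF, no
instrument simulation) — chosen so that VIP analysis of fitted models
highlights the visible/red-edge bands, as it does for real chlorophyll-
linked traits.

Traits are deterministic functions of the latents plus additive effects.
SPAD, N and LMA are direct transforms of their latents; A_sat, g_s,
Fv′/Fm′ and ΦPSII load on the standardized chlorophyll deviation (0.35–
0.55 of a cell SD), C on nitrogen, SLA negatively on dry matter.  Genotype
and year intercepts and residual/measurement noise are expressed as
fractions of each cell's SD (defaults 0.4 / 0.3 / 0.2) so that one setting
is meaningful across traits spanning four orders of magnitude, and their
squares sum below 1 so realized cell SDs track the configured ones.
Genotype effects on the physiological traits share a common "vigor"
factor (loading 0.7): a genotype with more chlorophyll and N also
photosynthesizes more and carries more leaf area.  Without this coupling a
genotype's A_sat effect would be spectrally invisible and no spectral
method could rank genotypes — the coupling is what makes the RUE-screening
question well-posed in the simulation, and its strength is a config knob.
LAI is generated directly from its cell targets (it is a canopy property,
not a leaf-latent transform) so canopy upscaling has an independent input.
Within-plot shoots are treated as exchangeable replicates.

Biomass at four stages (40 d after emergence, booting, anthesis + 7 d,
maturity) equals the genotype's true RUE × accumulated intercepted PAR
with multiplicative lognormal noise (CV 5 %, mean-one parameterization so
slope recovery is unbiased); daily irradiance rises through the season
(14 → 24 MJ m⁻² d⁻¹) and fAPAR follows a logistic canopy-closure curve
reaching 0.95.  True genotype RUE is correlated (default 0.8) with the
genotype's implied canopy-photosynthesis effect — the direct A_sat effect,
its chlorophyll-mediated part and the LAI effect combined — which is the
quantity canopy upscaling estimates.

What passing tests show, and what they do not: the generator guarantees
that spectra are genuinely predictive of the traits (chlorophyll-linked
traits almost fully, gas-exchange traits partially), so recovery tests
demonstrate the pipeline's correctness, not field-level accuracy.  Real
leaf spectra have correlated band noise, detector-splice artifacts,
water-status confounds and genotype × environment structure the generator
does not emulate; validation R² on synthetic data is therefore an upper
bound on what the same pipeline achieves in the field.  One consequence of
the simulated design worth knowing: per-layer validation sets are small
(~60 samples), so the maximum R² over three layers is upward-biased and
the combined model is expected to match the best layer within sampling
noise rather than dominate it on every seed.

## Pipeline choices

The combined strategy pools all layers into one spectra-only design — no
layer indicator column — so the model must explain layer differences from
reflectance alone; a layer-covariate variant can be explored by adding the
column upstream.  Outlier filtering is per trait within layer × stage
strata (layer/stage means differ enough that a global ±3 σ filter would
preferentially delete bottom-layer values); a global mode is available.
The 70/30 split is unstratified by default with a stratify-by-layer
option; the train size rounds half away from zero.  Stages are pooled
within each model with stage recorded in provenance.  Canopy upscaling
uses measured LAI by default (`lai_source="predicted"` switches to the
LAI model's predictions when LAI is among the modelled traits).  All
outputs are written with a fixed float format, and every random draw
derives from config seeds, so reruns are byte-identical.

Problem sizes in the test suite and the acceptance script (594-sample
trial, 10-fold CV, 100 BLUE-recovery replicates, 200 RUE trajectories)
were chosen as the smallest sizes at which the checked properties are
stable; nothing in the science depends on them.

## Known limitations

- The forward model is linear in its latents; saturation of strong
  absorption features (high-chlorophyll leaves) is not represented.
- The mixed model assumes homoscedastic Gaussian errors; no spatial field
  trend or incomplete-block structure is modelled.
- PLS2, kernel PLS and SIMPLS are out of scope (one trait at a time is the
  design), as are spectral preprocessing (derivatives, smoothing) and
  binary spectroradiometer formats.
- fAPAR interpolation is linear in time; rapid canopy changes between
  readings are smoothed over.
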