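# Methods

## Solar time and double-anchoring

Clock times live on the diel circle (24 h = 2π). Sunrise and sunset are
computed with the NOAA solar-position approximation (Julian-century
ephemeris, equation of time, zenith 90.833°), accurate to ~3 minutes
away from polar latitudes (|lat| < 66.5° enforced). Detection tables
may instead supply `sunrise`/`sunset` columns directly, which bypasses
the computation.

Double-anchoring maps each camera-day's times piecewise-linearly so the
day's sunrise/sunset coincide with the *anchors* — circular means of
sunrise and sunset over the camera-days of the analysis unit. The map
is a continuous circular bijection (daylight arc → mean daylight arc,
night arc → complement) and is inverted exactly by
`inverse_double_anchor`. Anchors are computed per analysis unit —
per region for the regional analysis, per landscape for the
landscape-level fits — and the scope is configurable; circular rather
than arithmetic means are used so midnight-spanning values average
correctly. All times are local standard time; daylight-saving
transitions are the caller's responsibility (winter sampling windows
avoid them).

## Circular KDE and the activity level

The density is a von Mises kernel mixture
f̂(x) = (1/n) Σᵢ K(x − tᵢ; k_bw) evaluated on a 512-point grid
(configurable; integral and peak errors are far below the 0.01
reporting precision). The kernel concentration follows Taylor's plug-in
rule,

    k_bw = (3 n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²))^(2/5) × adjust,

where κ̂ is the largest of the concentrations matching the first four
trigonometric moments (solving I_k(κ)/I₀(κ) = |mean e^{ikt}| for
k = 1..4). Order 1 alone is the maximum-likelihood von Mises fit, but
it degenerates for bimodal (crepuscular) samples whose first moment
nearly cancels; order 2 rescues that case, and order 4 covers densities
with distinct modes near all four of 00/06/12/18 h, whose opposing-pair
symmetry can cancel orders 1–3 simultaneously. Each squared moment
modulus is soft-thresholded at its Rayleigh significance bound (under
uniformity n·ρ_k² ~ Exp(1); the positive-part shrinkage
ρ² → max(ρ² − c/n, 0) with c the Bonferroni 5% bound over the orders
tested), since otherwise pure noise in the higher-order moments
sharpens the kernel on uniform data and pushes the flat-density level
estimate down to ~0.93 instead of 1; with shrinkage, moments consistent
with uniformity contribute nothing and strong structure is essentially
unaffected. The bandwidth `adjust` multiplier defaults to 1.5,
the value commonly used for activity-level estimation with this
estimator.

The activity level is p̂ = 1/(2π·max f̂) ∈ (0, 1]: 1 for a flat
density (active all day), smaller as activity concentrates. The grid
maximum is refined by circular parabolic interpolation through the
argmax and its neighbours, which removes the dependence of the estimate
on where the peak falls relative to grid points (and with it a ~1e-4
rotation non-invariance). For von Mises(κ) data the estimand is
I₀(κ)e^(−κ) in closed form, used as the test oracle.

**Small-sample behaviour.** Kernel smoothing perturbs the peak, so p̂
carries some bias at small n (within about ±0.04 at 300 detections for
crepuscular shapes, shrinking as the plug-in bandwidth sharpens with
n; per-landscape mean absolute error ≈ 0.03 at the ~500-detection
scale on synthetic data). Pooled regional estimates (thousands of
detections) sit well inside the accurate regime. Note that pooling
heterogeneous landscapes flattens the mixture, so a region's pooled
level legitimately exceeds the mean of its landscape levels.

**Bootstrap.** Uncertainty comes from an n-out-of-n nonparametric
bootstrap over detection times (1000 replicates by default; percentile
intervals). The kernel concentration is held at the full-sample value
across replicates, which makes each replicate density an exact weighted
average of precomputed kernel columns (a multinomial-weight fast path);
re-selecting the bandwidth per replicate is available as an option.
Resampling is at the detection level; the composition bootstrap
resamples all four fractions jointly so every replicate composition
sums to 1.

## Time-of-day categories and the composition

Morning and evening are the 4-h windows centred on the mean sunrise and
sunset; daytime and night fill the gaps; boundaries are half-open
[t1, t2) so the four arcs tile the circle exactly. Anchors closer than
4 h (overlapping windows) raise an error. Fractions are computed by
composite trapezoid on a ≥ 2048-point refinement with periodic
interpolation, then renormalized to sum to exactly 1; they are
fractions *of the total density* (the Dirichlet response scale), with
fraction × level available as a derived quantity for plotting.

## Wald comparisons and Holm adjustment

W = (AL₁ − AL₂)²/(SE₁² + SE₂²) referred to χ²(1); survival
probabilities are floored at the smallest positive double so extreme
statistics keep p in (0, 1]. Holm's step-down multiplies the i-th
smallest p by (m − i + 1), enforces monotonicity, caps at 1. Three
comparison families are each adjusted separately: levels between
regions; each category's fraction between regions (one family of 12 for
3 regions × 4 categories); fractions between categories within regions
(one family of 18). A single global family is available via
configuration.

## Covariates

Twig density D = total twigs / total 1-m² quadrats. Transects per
forest patch: the smallest NT with NT² > A/2 (strict inequality; A in
ha). Browse selection: per species, a 1-df Pearson goodness-of-fit of
consumed counts (species vs all others) against availability
proportions; a species is *avoided* only when consumption is
significantly below expectation (p ≤ 0.05 and observed < expected) —
neutral and preferred species are *non-avoided* and their pooled twig
density is the natural-food covariate. No continuity correction
(configurable). Landscape twig density aggregates patch densities by
area weighting (configurable). All regression predictors are z-scored
with the sample SD.

## Hierarchical regressions

Beta: level_j ~ Beta(μ_jφ, (1−μ_j)φ), logit(μ_j) = b₀ + x_j'b +
u_region(j). Dirichlet: y_j ~ Dirichlet(μ_jφ) with softmax link and
night as reference; three per-category region intercepts share one
σ_u. Priors: Student-t(3, 0, 2.5) on intercepts and slopes (the
common weakly-informative default for standardized predictors), half-t
on σ_u, Gamma(0.01, 0.01) on φ. Interaction models include both main
effects plus the product of the standardized predictors. Landscapes
resampled across years enter as separate rows; no year effect is
modelled.

Posteriors are sampled with an affine-invariant ensemble sampler
(emcee) using differential-evolution moves (80% DE, 20% snooker), a
non-centered parametrization of the random intercepts (u = σ_u·z), and
log transforms of σ_u and φ with prior Jacobians. Defaults: ≥ 90
walkers, 3000 steps, 1500 discarded, thinned by 5; walkers are grouped
into 3 chains for R̂ diagnostics (threshold 1.01; non-convergence is
flagged on the fit and in the report, never silent). These settings
were sized so that R̂ < 1.01 holds across the candidate sets on
synthetic data at the study's scale (~50 rows); the tests use smaller
step counts where only point estimates matter.

Model comparison uses PSIS-LOO (arviz) from the pointwise
log-likelihood, with stacking weights by default (pseudo-BMA+
optional) and evidence ratios max-weight/weight (support declared
below 3). Inference uses equal-tailed 89% credible intervals; a
predictor is "strong" when its interval excludes zero. Compositions
containing zeros raise an error by default; an explicit
`zero_replacement` (e.g. 1e-4, with renormalization) is opt-in.

## Synthetic data generator

The generator mirrors the target study design: 3 regions × 16
landscapes (48 unique), 21 cameras per landscape, negative-binomial
camera counts (mean 26, dispersion 1.5; ≈ 540 detections per landscape,
matching the scale of the field design), a 14-day late-winter window,
and solar-symmetric 06:00/18:00 anchor days with ±20 min site jitter.
Covariates: log-normal buildings and road length, gamma twig density,
uniform agricultural area spanning ~0.05–0.80 km² (bracketing the
0.13/0.42/0.72 km² −1 SD/mean/+1 SD settings of the target gradient),
log-normal deer density (mean ≈ 9–10 deer/km²). True regression
structure defaults: level intercept −0.32 (mean level ≈ 0.42) with a
buildings effect of 0.12; pattern intercepts giving a night-heavy
composition and twigs × agriculture interactions of −0.32 / −0.31 /
−0.09 on morning/daytime/evening — the effect structure the pipeline is
designed to detect. Region SD 0.10, φ_level 200, φ_pattern 150.

Each landscape's circular density is a four-component von Mises mixture
centred on the category midpoints: component weights solve the 4×4
linear system equating category integrals to the target composition,
and the shared concentration is bisected so the realized peak level
approaches the target. *Realized* level and composition (dense-grid
evaluation, parabolic peak) are recorded as ground truth, decoupling
generator imperfection from estimator bias. Detections are inverse-CDF
draws from the density, mapped to clock times by inverting the
anchoring map per camera-day. An optional burst mode triplicates rows
to exercise encounter de-duplication.

What the generator does **not** emulate: camera-level detection
heterogeneity tied to habitat, serially correlated encounters (animals
lingering), imperfect photo classification, moonlight/weather
covariates, and day-length trends within the window. Passing tests
therefore demonstrate estimator and sampler correctness under the
assumed model, not robustness to those field realities.

## Numerical choices and limitations

- Grid 512 for estimation, 4096 for generator truth; composition
  integrals on ≥ 2048 points; refinement by 4× moves fractions < 1e-4.
- Encounter de-duplication (default 15-min rolling window per camera)
  is meant for burst-prone field data. On data whose encounters are
  already independent it preferentially thins peak-hour detections and
  inflates levels by ~0.05; disable it (`dedup_window_min: 0`) when
  encounters are pre-deduplicated, as the synthetic tests do.
- The trig-moment bandwidth rule is blind to structure whose first four
  moments all cancel (e.g. an exactly 8-fold symmetric density); such
  shapes do not occur in diel data.
- Stacking weights are winner-take-most: a clearly best model takes
  weight ≈ 1, so synthetic weight tables look more extreme than
  field-data ones where candidate models are closer.
- The Wald comparisons inherit the level estimator's n-dependent bias;
  comparing regions with very different detection counts at small n can
  produce systematic (not just stochastic) differences.
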