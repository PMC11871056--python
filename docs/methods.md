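# Methods

## The system being modelled

Three honeyeater species feed at a bird-pollinated shrub whose tubular
flowers place anthers and stigma in the bird's path to the nectar. Each
captive trial pairs one pollen-donor flower (anthers intact) with one
pollen-receiver flower (emasculated, stigma only); high-speed video
(800 fps) yields anther-contact frames, feeding-bout frames, and lick
counts, a scaled dorsal still yields the pollen-patch polygon, and
microscopy of the receiver's stigma yields a pollen-grain count. Camera
traps at wild plants record, per visit, the visiting species and the
number of flowers probed.

## Trait matching

Matching is the ratio of a bird measurement to a floral measurement
(e.g. bill length / total corolla length): 1 means equal sizes, <1 the
flower is larger, >1 the bill is larger. Donor interactions use
{BL/TCL, BL/ECL, BW/CW, BL/ACO, BL/AN, tarsus}; receiver interactions
swap the anther distances for stigma distances {BL/SCO, BL/SN}. Anther
distances exist only on donor flowers and stigma distances only on
receivers, hence two parallel PCAs. Tarsus enters raw (then
standardised) as a body-size covariate; whether a size-corrected
transform would be preferable is an open design question we resolve in
favour of the simplest encoding.

Each PCA is run on the pooled bird × flower interactions (one row per
trial-flower), centred and scaled by the sample (n−1) SD, i.e. an
eigendecomposition of the correlation matrix. Component signs are fixed
by making the largest-magnitude loading of each component positive;
downstream models use absolute scores, so results do not depend on this
convention, but plots and tests need determinism. |PC| = 0 is the
closest match; larger values mean more mismatch in either direction.

## Response variables

* anther-contact duration (s) = contact frames / 800; all contact frames
  are summed when contact is intermittent.
* pollen-patch area (mm²) = shoelace polygon area in px² divided by the
  squared px/mm image scale. Degenerate polygons (<3 vertices) have
  area 0; a self-intersecting outline triggers a WARN-prefixed warning
  and the magnitude of the signed area is used.
* feeding duration (s) and feeding efficiency (µL/s) = 30 µL / duration.
  The nectar load is standardised to 30 µL in every trial, so
  efficiency × duration equals the load exactly. By default the
  receiver-visit film provides the bout; `feeding_source` switches to
  the donor film or the pooled pair (the latter matches how both visit
  types enter the matching-vs-efficiency model).
* licking rate (licks/s) = lick count / bout duration.

Per-species summaries report mean ± SE with n = number of trials,
matching trial-level plotting; aggregation to birds first is available
(`per_bird=True`).

## Mixed models

Eight log-link random-intercept GLMMs (`MODEL_SPECS`):

| model | response | fixed effects | family | random intercepts |
|---|---|---|---|---|
| mod1 | stigma pollen count | species | NB2 | bird |
| mod2 | anther contact (s) | species | Tweedie + ZI(species) | bird |
| mod3 | patch area (mm²) | species | Tweedie + ZI(species) | bird |
| mod4 | feeding duration (s) | species | Gamma | bird |
| mod5 | feeding efficiency (µL/s) | species | Gamma | bird |
| mod6 | patch area (mm²) | donor \|PC1\|, \|PC2\| | Tweedie | species + bird |
| mod7 | stigma pollen count | patch area, receiver \|PC1\|, \|PC2\| | NB2 | species + bird |
| mod8 | feeding efficiency (µL/s) | \|PC1\|, \|PC2\| (role-matched, both visit types) | Gamma | species + bird |

|PC| predictors enter unstandardised, so coefficients read as change per
unit PC score. A pre-check (type-III ANOVA of deposition on trial ×
species with sum-to-zero contrasts) verifies trial number can be
omitted from the models.

Fitting maximises the Laplace-approximated marginal likelihood. The
random-effects mode is found by damped Newton iterations — a vectorised
per-group scalar update for a single grouping factor, a dense solve for
the small nested (species + bird-within-species) structure — and the
outer parameters (fixed effects, log dispersion, transformed Tweedie
power, zero-inflation logits, log random-effect SDs) are optimised by
L-BFGS-B with bound constraints (Tweedie power is kept in (1.02, 1.98)
by a scaled logistic transform; log SDs in [−6, 2.5], so a variance
component can collapse to an effectively-zero boundary). Convergence is
reported on every fit and non-convergence warns loudly; ties between
restarts are not needed because the optimiser is deterministic given
the data and starting values (method-of-moments dispersion, least
squares on log response for the coefficients).

The Tweedie density has no closed form; for y > 0 it is evaluated by
the compound Poisson–gamma series in log space, summed with logsumexp
over a window that spans twice the dominant index plus a fixed margin
(terms beyond the window are below the 40-log-unit truncation level).
The mean-independent series term is cached per (φ, p), so the inner
Newton iterations and most outer gradient steps avoid the series
entirely. Zero inflation adds a per-species structural-zero probability
π with the mixture mass π + (1−π)·e^(−λ) at zero.

Standard errors come from the inverse of a finite-difference Hessian of
the negative marginal log likelihood at the optimum (all outer
parameters jointly). Type-III tests are Wald χ² on each term's
coefficient block with all other terms present. Pairwise species
contrasts are link-scale differences with Tukey (studentized-range)
adjustment at asymptotic df; with two levels the adjusted p equals the
two-sided Wald p. Cohen's d is computed on the raw response with the
n−1-weighted pooled SD, deliberately not on the link scale.

Marginal and conditional R² partition the latent log-scale variance
into fixed-effect linear-predictor variance, summed random-intercept
variances, and an observation-level distribution variance: trigamma
ψ₁((1/μ̄ + 1/θ)⁻¹) for NB2, ψ₁(shape) for Gamma, and the lognormal
approximation ln(1 + φ·μ̄^(p−2)) for Tweedie, which has no trigamma
form; μ̄ is the mean fitted response including the lognormal
random-effect correction. With only three species levels, the
species-level variance in mod6–mod8 is weakly identified and often
shrinks to the boundary; the structure is kept for fidelity to the
stated models.

## Landscape permutation estimator

For one run, every visit of species s receives a deposition value drawn
uniformly with replacement from the per-flower stigma counts measured
for s (zero-deposition trials stay in the pool — they are measured
outcomes, and dropping them would bias the totals upward). The visit's
contribution is the drawn value × flowers probed; the per-species mean
over visits is the per-plant estimate and the sum the landscape total.
R = 100 runs by default. Under this scheme the draw is independent of
the visit, so E[mean per plant] = mean(pool) × mean(flowers probed) and
E[landscape total] = mean(pool) × Σ flowers probed, with exact variances
var(pool)·Σfᵢ²/n² and var(pool)·Σfᵢ²; `closed_form_expectation`
implements these and `enumerate_expectation` verifies them exhaustively
on tiny instances. Whether the value should be redrawn per probed
flower rather than per visit is ambiguous in principle; per-visit
assignment is primary and `per_flower=True` provides the alternative
(identical expectation, smaller variance). Runs enter the species
ANOVA as i.i.d. observations, which understates the uncertainty
contributed by the finite experimental pool — the reported SEs describe
the permutation distribution, not full sampling uncertainty.

## Synthetic data generator

The generator emulates the study design at its actual scale: 3 species
with 3/9/8 individuals, 5 two-part trials each (100 trials, 200 flower
visits), visit counts 1258/1495/146 and mean flowers probed
5.6/5.4/5.2. A single root seed fans out to per-stage child streams via
`SeedSequence` spawn keys, so adding a stage never perturbs earlier
stages and fixed seeds give byte-identical tables.

Distributional choices and defaults:

* **Bird morphometrics**: multivariate normal around species means with
  a diagonal covariance (4% relative SD, 8% for mass), truncated at a
  0.1 mm floor. Normality is the minimal assumption given means ± SD;
  the default means put the large species' bill above the flower in
  both length and width, the small species' below, and the intermediate
  species astride a ratio of 1 — the qualitative configuration that
  drives the matching results.
* **Per-flower deposition**: NB2 with per-species means 4.6/22.6/47
  grains (the per-plant permutation means divided by mean flowers
  probed) and θ = 0.5, consistent with the heavy overdispersion the
  count models assume.
* **Patch area and anther contact**: zero-inflated Gamma (structural
  zero probabilities 0.30/0.10/0.10 for patches); non-zero patches are
  rendered as star-shaped polygons with bounded angular gaps (which
  guarantees a simple outline) scaled to the drawn area at a random
  px/mm image scale.
* **Feeding bouts**: Gamma with shape 9 and species rates giving ~1.5 s
  for the large species and ~3 s for the small ones; lick counts are
  Poisson at 5–8 licks/s of the realised bout.
* **Individual heterogeneity**: independent per-bird log-normal
  intercepts per response family, SD 0.7 (deposition), 0.8 (patch),
  0.25 (feeding), 0.5 (contact). These magnitudes make the
  conditional−marginal R² gap of the fitted models match the variance
  partitioning typical of repeated measures on individual birds in this
  system: strong individual signal in pollen handling, weak in feeding
  performance.
* **Visits**: flowers probed per visit is 1 + Poisson(mean − 1), so
  every visit probes at least one flower.

What the generator does **not** emulate: site effects on floral
morphology or visitation, temporal autocorrelation across a bird's five
trials (pollen carry-over is excluded by design after the trial-effect
pre-check), any built-in dependence of deposition on patch area or
matching scores beyond what species identity induces, and pollen
loss between flowers. Passing tests therefore demonstrate that the
estimators and models recover the structure they assume, not that real
data satisfy those assumptions.

Because the per-species pools are small (15–45 trials) and heavily
overdispersed, a given seed's *realised* pool means can occasionally
lose the configured species ordering. The rank-reversal check therefore
constructs its replicates conditionally: pool draws are rejected until
the realised per-flower means carry the qualitative structure (highest
depositor has fewest visits, moderate depositor the most), and the
≥95% criterion then measures the estimator's ranking behaviour given
that structure rather than the generator's sampling noise.

## Problem sizes used in the test suite

Calibration checks fit each family at ten times the filmed-bird count
(30/90/80 birds × 5 trials) for 200 replicates, and the type-III Wald
type-I error runs 1000 null replicates at 45 birds; the rank-reversal
check uses 200 replicates of the full study-scale dataset with R = 10
permutation runs each, and the estimator's Monte-Carlo check uses
R = 10⁴ runs. These sizes give binomial/Monte-Carlo resolution well
inside the asserted bands while keeping the suite quick to run.

## Known limitations

* Wald inference at the study's own scale (3/9/8 birds) is asymptotic;
  the type-I error simulation shows mild anticonservatism (~0.067 at
  nominal 0.05) at 45 birds, and small-sample corrections (Kenward–
  Roger-style) are not implemented.
* The Tweedie R² uses a lognormal approximation rather than an exact
  latent-scale variance.
* The permutation ANOVA treats runs as observations (see above).
* No spatially explicit foraging, pollen carry-over, or seed-set
  modelling; the landscape totals are deposition budgets, not fitness.
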