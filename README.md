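# pollscape

Quantitative analysis of plant–pollinator trait matching for nectar-feeding
birds: from bill–corolla morphometric ratios, through per-visit pollen
transfer and feeding efficiency models, to permutation-based scaling of
per-flower pollen deposition onto camera-trap visitation records.

The package is written for pollination ecologists who measure per-visit
pollination effectiveness in captive or semi-captive trials (high-speed
video of birds feeding at real flowers) and who monitor wild visitation
with camera traps, and who want to connect the two: does morphological
matching between bill and corolla predict pollen transfer and nectar
extraction, and do per-flower differences between pollinator species
survive scaling to whole plants and the landscape?

## What it computes

**Trait matching.** For each bird × flower interaction, ratios of bird to
floral linear morphometrics — BL/TCL, BL/ECL, BW/CW, plus BL/ACO and
BL/AN on pollen-donor flowers (anthers intact) or BL/SCO and BL/SN on
pollen-receiver flowers (emasculated, stigma only) — with tarsus length
as a body-size covariate. A ratio of 1 means bill and floral structure
are the same size. The ratio set is reduced by a centred-and-scaled
(correlation-matrix) PCA; models use |PC score|, where 0 is the closest
match and larger magnitudes mean more mismatch in either direction.

**Transfer and feeding metrics.** Frame counts from 800-fps video become
durations (s); the digitised pollen-patch polygon becomes an area (mm²)
via the shoelace formula and the px/mm image scale; feeding efficiency
is the standardised 30 µL nectar load divided by bout duration (µL/s);
licking rate is licks per second of the bout.

**Mixed models.** Eight random-intercept GLMMs with a log link, fitted by
Laplace-approximated maximum likelihood: negative binomial (NB2,
Var = μ + μ²/θ) for stigma pollen counts; Tweedie (compound
Poisson–gamma, power p ∈ (1,2), optionally with a per-species structural
zero probability) for anther-contact durations and patch areas; Gamma
for feeding durations and efficiencies. Inference follows the standard
mixed-model workflow: type-III Wald χ² tests, Tukey-adjusted pairwise
contrasts, Cohen's d on the raw response, and marginal/conditional R²
with the trigamma observation-level variance.

**Landscape scaling.** Each camera-trap visit is assigned a per-flower
deposition value drawn uniformly with replacement from that species'
measured stigma counts, multiplied by the flowers probed in the visit;
the per-species mean over visits estimates deposition per plant visit
and the sum estimates the landscape total. Repeating the assignment R
times (default 100) gives sampling distributions that are compared
across species by ANOVA, Tukey contrasts, and Cohen's d. A closed-form
module gives the exact expectation and variance of both estimators.

A synthetic-data generator reproduces the statistical structure of the
study design (3 honeyeater species with 3/9/8 individuals × 5 two-part
trials; 1258/1495/146 camera-trap visits) so the full pipeline is
testable end to end.

## Worked example

```python
import pollscape as ps
from pollscape.landscape import deposition_pools, run_permutations, summarize

data = ps.generate_dataset(seed=1)          # 3 species, 3/9/8 birds, 5 trials each
pools = deposition_pools(data["trials"])    # measured per-flower stigma counts
runs = run_permutations(data["visits"], pools, R=100, seed=1)
print(summarize(runs).to_string(index=False, float_format="%.1f"))

fit = ps.fit_glmm(ps.MODEL_SPECS["mod1"], ps.compute_metrics(data["trials"]))
print("species effect p =", round(ps.type3_test(fit, "species"), 4))
r2 = ps.r2_nakagawa(fit)
print("marginal R2 =", round(r2.marginal, 3), " conditional R2 =", round(r2.conditional, 3))
```

prints

```
                 species   R  mean_per_plant_mean  mean_per_plant_se  landscape_total_mean  landscape_total_se
Acanthagenys rufogularis 100                 27.9                0.1               35081.7               181.5
        Ptilotula ornata 100                104.8                0.7              156688.0              1034.3
      Purnella albifrons 100                263.9                2.9               38527.7               428.6
species effect p = 0.0013
marginal R2 = 0.127  conditional R2 = 0.237
```

*Purnella albifrons* deposits the most pollen per plant visit (264 grains
on average: it has the highest per-flower deposition), yet *Ptilotula
ornata* dominates the landscape total (157k grains: it was recorded on
ten times as many visits) — per-visit effectiveness and landscape-level
contribution rank the species differently. The NB2 model confirms the
species differences in per-flower deposition (p = 0.0013); fixed effects
explain 13% of the latent-scale variance and fixed plus per-bird random
intercepts 24%.

The same pipeline runs from the shell:

```bash
pollscape all --seed 1 --out results/
pollscape landscape --seed 1 --out results/ --runs 100
```

Outputs are plain CSV with a provenance header (version, seed, config
hash) plus a machine-readable `manifest.json`; column names and units
are documented in `docs/data_dictionary.md`.

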