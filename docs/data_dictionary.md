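# Data dictionary

All tables are plain CSV (UTF-8, "." decimal) whose first line is a
provenance comment (`# pollscape v<version> seed=<seed>
config_hash=<hash>`).

## birds.csv — one row per captured individual

| column | type | unit | description |
|---|---|---|---|
| bird_id | text | — | unique individual code |
| species | text | — | scientific name |
| mass | float | g | body mass |
| wing_chord | float | mm | carpal joint to longest primary |
| tarsus | float | mm | intertarsal joint to foot; body-size covariate |
| bill_length | float | mm | feather base to tip |
| bill_width | float | mm | at proximal side of nares |
| bill_depth | float | mm | dorsal to ventral at nares |

## flowers.csv — one row per experimental flower

| column | type | unit | description |
|---|---|---|---|
| flower_id | text | — | unique flower code |
| plant_id | text | — | source plant |
| role | text | — | `donor` (anthers intact) or `receiver` (stigma only) |
| TCL | float | mm | total corolla length |
| ECL | float | mm | effective corolla length (nectar-accessible) |
| CW | float | mm | corolla width |
| ACO | float | mm | anthers to corolla opening (donor only) |
| AN | float | mm | anthers to nectary (donor only) |
| SCO | float | mm | stigma to corolla opening (receiver only) |
| SN | float | mm | stigma to nectary (receiver only) |

## trials.csv — one row per two-part trial (donor visit + receiver visit)

| column | type | unit | description |
|---|---|---|---|
| bird_id | text | — | individual |
| species | text | — | species |
| trial_number | int | — | 1–5 within bird |
| donor_flower_id / receiver_flower_id | text | — | flowers used |
| anther_contact_frames | int | frames | summed contact at 800 fps |
| feeding_frames_donor / feeding_frames_receiver | int | frames | feeding-bout length per visit |
| lick_count | int | licks | tongue cycles during the receiver bout |
| patch_polygon | text | px | `"x1 y1;x2 y2;…"` vertices; empty = no patch |
| image_scale | float | px/mm | dorsal-still calibration |
| stigma_pollen_count | int | grains | pollen deposited on the receiver stigma |
| nectar_volume | float | µL | standardised load (30) |

## visits.csv — one row per camera-trap plant visit

| column | type | unit | description |
|---|---|---|---|
| visit_id | text | — | unique visit code |
| species | text | — | visiting species |
| site_id | text | — | camera site |
| flowers_probed | int | flowers | ≥ 1, counted from video |

## Derived outputs

* **matching.csv** — per trial × flower role: matching ratios (BL_TCL,
  BL_ECL, BW_CW, BL_ACO, BL_AN or BL_SCO, BL_SN; dimensionless), tarsus
  (mm), PC1/PC2 scores and their absolute values.
* **metrics.csv** — per trial: stigma_pollen_count (grains),
  anther_contact_s (s), patch_area_mm2 (mm²), feeding_duration_s (s),
  feeding_efficiency_ul_s (µL/s), licking_rate_s (licks/s).
* **models.csv** — one row per model × term plus one per pairwise
  species contrast: link- and response-scale coefficients, type-III p,
  Tukey-adjusted p, Cohen's d, marginal/conditional R², convergence.
* **permutations.csv** — per run × species: mean_per_plant (grains) and
  landscape_total (grains).
* **landscape_summary.csv** — per species: mean ± SE over runs of both
  permutation metrics.
* **manifest.json** — version, seed, config hash, stages executed, PCA
  variance fractions, trial-effect p values, landscape comparisons.
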