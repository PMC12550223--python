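# CSV data dictionary

All tables are plain RFC-4180 CSV with a header row.  `read_*` functions
validate types and invariants and report the offending row and column.

## parameters.csv

One row per coefficient draw (`iteration_id` 1..N).  Probabilities are on
the logit scale; masses in grams; hydroperiod in days; rainfall in mm.
Covariates are centered at the constants carried in the last three columns.

| column | meaning | constraint |
| --- | --- | --- |
| `iteration_id` | draw index (unit of uncertainty propagation) | integer |
| `surv_intercept`, `surv_mass_slope` | post-metamorphic annual survival, logit-linear in `mass − mass_center` | — |
| `growth_intercept`, `growth_slope`, `growth_sd` | next-mass kernel `N(a + b·mass, sd)` (g) | `growth_sd ≥ 0` |
| `maturity_intercept`, `maturity_mass_slope` | maturation probability, logit-linear in centered mass | — |
| `fert_intercept`, `fert_mass_slope` | clutch size (eggs), linear in mass, truncated at 0 | — |
| `breeding_prob` | baseline per-adult annual breeding probability | in [0, 1] |
| `larv_intercept`, `larv_hydro_slope`, `larv_his_slope`, `larv_hydro_his_interaction` | larval survival, logit-linear in centered hydroperiod, HIS, and their product | — |
| `meta_intercept`, `meta_hydro_slope`, `meta_his_slope`, `meta_sd` | metamorph mass (g), linear in centered hydroperiod and HIS | `meta_sd ≥ 0` |
| `dd_surv_slope` | slope of ln(larval survival) on ln(egg density) | ≤ 0 |
| `dd_mass_slope` | slope of ln(metamorph mass) on ln(egg density) | ≤ 0 |
| `ref_egg_density` | egg density (eggs·m⁻³) at which density adjustments are the identity | > 0 |
| `rain_breed_intercept`, `rain_breed_slope` | breeding fraction of females, logit-linear in `dec_jan_mm − rain_center` | — |
| `mass_center`, `hydro_center`, `rain_center` | centering constants (g, days, mm) | constant across rows from one source |

## rainfall.csv

One row per historical year.

| column | meaning | constraint |
| --- | --- | --- |
| `year_id` | year label (echoed into per-year records) | integer |
| `dec_jan_mm` | cumulative December–January precipitation (mm) | ≥ 0, finite |
| `oct_jun_mm` | cumulative October–June precipitation (mm) | ≥ 0, finite |

## results.csv (per experiment run)

One row per scenario × draw: `mode`, `hydroperiod_days`, `prop_hybrid`,
`volume_m3`, `init_n`, `iteration_id`, then the mode's statistics among
`lambda_hat`, `k_hat`, `n_100`, `stable_size`, `final_his`, `extinct`
(unused statistics empty).  The removal sweep instead writes one row per
strategy × scenario with the five `strategy_*` columns, both arms' final
HIS, and `delta_his_pct`.
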