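# pondipm

Individual-based integral projection model (IPM) for a hybridizing
pond-breeding salamander system: an endangered native tiger salamander
(California tiger salamander, CTS) that interbreeds with an introduced
congener (barred tiger salamander, BTS), producing fertile hybrids whose
larvae outperform natives — especially in ponds with artificially long
hydroperiods.  The package is aimed at conservation modellers evaluating
hydroperiod management and targeted hybrid-removal programs.

## What it computes

Each simulated salamander carries a sex, age, body mass *m* (g), and a
hybrid index score HIS ∈ [0, 1] (proportion of non-native ancestry;
natives are conventionally 0.05).  Vital rates are continuous functions of
mass and environment, applied individual-by-individual each year:

* survival `logit s(m) = a_s + b_s (m − m̄)`, with individuals older than
  15 years coded dead;
* growth `m′ ~ N(a_g + b_g m, σ_g)`; maturation
  `logit p(m) = a_m + b_m (m − m̄)` (absorbing);
* fertility `max(0, a_f + b_f m)` eggs; offspring HIS is the mid-parent
  mean; mates are assigned uniformly at random;
* larval survival to metamorphosis
  `logit S = a_l + b_h (h − h̄) + b_g·HIS` in hydroperiod *h* (days), and
  metamorph mass linear in the same covariates;
* density dependence (log–log): `ln S` and `ln mass` shift by
  `β·(ln D − ln D_ref)` with egg density `D = eggs / pond volume`, exactly
  the identity at the reference density;
* environmental stochasticity: December–January rainfall sets the
  fraction of females breeding (logit-linear); October–June rainfall sets
  the fraction of larvae metamorphosing through a piecewise-linear ramp —
  0 at ≤ 404.5 mm (complete reproductive failure), 1 at ≥ 674.5 mm.

From 100-adult ponds swept over hydroperiod (80–120 d) × initial hybrid
proportion (0–1) scenarios, with one run per vital-rate coefficient draw,
the experiments return:

* **λ** — intrinsic growth rate, `exp(slope of ln N_t on t)` over
  post-transient years (density-independent runs);
* **K** — carrying capacity, median adult count over the final quarter of
  density-dependent century runs;
* **viability** — persistence against a 3-individual quasi-extinction
  threshold under rainfall resampled from a historical series, plus stable
  size as a percent of K;
* **ΔHIS** — percent change in population HIS under a removal strategy
  (detection threshold, capture probability, screening budget, program
  length, HIS removal threshold) relative to a paired no-removal baseline
  sharing the same environment; negative ΔHIS is management success.

## Worked example

```python
from pondipm import (SyntheticConfig, generate_parameter_draws,
                     generate_rainfall_series, run_density_independent,
                     run_pva, default_scenarios)
from pondipm.experiments import results_to_frame

draws = generate_parameter_draws(SyntheticConfig(n_draws=20, rng_seed=1))
rain = generate_rainfall_series(SyntheticConfig(rng_seed=1), 100)
scenarios = default_scenarios(hydroperiods=[80, 100, 120], prop_hybrids=[0.0, 1.0])

lam = results_to_frame(run_density_independent(scenarios, draws, n_years=8, rng_seed=1))
print(lam.groupby(["hydroperiod_days", "prop_hybrid"]).lambda_hat.median().round(2))
```

```
hydroperiod_days  prop_hybrid
80                0.0            0.79
                  1.0            0.84
100               0.0            0.91
                  1.0            1.05
120               0.0            1.42
                  1.0            2.13
```

Median λ < 1 in 80-day ponds (declining populations) and > 1 at 120 days,
with all-hybrid ponds growing faster than all-native ones at every
hydroperiod — the qualitative pattern that motivates using short
hydroperiods to suppress hybrids and long ones to bolster secure native
populations.  Adding rainfall stochasticity:

```python
pva = results_to_frame(run_pva(scenarios, draws, rain, rng_seed=1))
print(pva.groupby("hydroperiod_days").extinct.mean().round(2))
```

```
hydroperiod_days
80     1.00
100    0.08
120    0.00
```

Every 80-day population crosses the quasi-extinction threshold within a
century; 120-day ponds never do under these coefficients.

The same pipeline is scriptable from the shell (`pondipm synth-params`,
`synth-rain`, `lambda`, `capacity`, `pva`, `removal`, `summarize`); each
subcommand writes a results CSV and a `run_metadata.txt` sufficient to
regenerate it bit-identically.

## Layout

- `src/pondipm/params.py` — coefficient draws, rainfall series, synthetic
  generators, CSV schemas, ML + bootstrap regression fitting
- `src/pondipm/vital_rates.py` — the demographic-rate functions
- `src/pondipm/population.py` — the 13-step annual cycle, pairing,
  recruitment, hybrid removal
- `src/pondipm/experiments.py` — λ / K / PVA / removal experiments and the
  deterministic mean-field oracle
- `src/pondipm/summaries.py` — mixed-model effect summaries, percent-change
  and scaled-effect-ratio statistics
- `src/pondipm/cli.py` — the `pondipm` command
- `docs/methods.md` — model description, assumptions, parameter defaults,
  and design notes
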