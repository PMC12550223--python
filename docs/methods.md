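# Methods

## The model

`pondipm` is an individual-based implementation of a size-structured
integral projection model (IPM) for a pond-breeding salamander whose
populations mix native and non-native ancestry.  Rather than iterating a
projection kernel, the package tracks every individual's sex, age, body
mass (g), maturity state, and hybrid index score (HIS — the proportion of
the genome of non-native origin, in [0, 1]) and applies the vital-rate
functions stochastically each year, in a fixed 13-step order: survival
(with a hard maximum age of 15), growth, maturation (absorbing), fertility,
breeding status, death removal, optional hybrid removal, breeder selection
(with rainfall thinning of females in stochastic mode), random mate
pairing (each female one male, males with replacement), larval survival,
fecundity (fertility × larval survival), metamorph creation with
mid-parent HIS, and metamorph mass assignment.  The yearly census
(juveniles + adults, including the year's metamorphs) closes the cycle.

Assumptions worth stating explicitly: random mating (no assortment by
ancestry), neutral diagnostic loci (HIS changes only through inheritance
and removal, never selection on individual loci), a closed pond (no
immigration), a 50:50 primary sex ratio independent of genotype, and
temperature/terrestrial-stage effects outside the model.

## Vital-rate parameterization

All probabilities are logit-linear; growth, fertility, and metamorph mass
are identity-linear.  Mass, hydroperiod, and December–January rainfall
covariates enter centered (at 15 g, 100 d, 150 mm by default), with the
centering constants stored in the coefficient table so external
coefficient sets remain portable.  One `ParameterDraw` holds the complete
coefficient set; running each simulation once per draw propagates
parameter uncertainty into every population statistic, emulating posterior
propagation.  Where an external coefficient source leaves its link functions or mass
transformations unstated, the configurable forms here are a declared
approximation; suppliers must provide coefficients on these scales.

Density dependence acts on the two larval rates only, log–log: the
hydroperiod/HIS predictions are treated as the values at a reference egg
density `D_ref` (eggs·m⁻³; egg density = total eggs laid / pond volume),
and `ln S` and `ln mass` shift by `slope × (ln D − ln D_ref)` with
non-positive slopes.  The adjustment is the exact identity at `D_ref`;
zero density is evaluated at a floor of `D_ref × 10⁻³` to keep the
logarithm defined, and survival is clipped into (0, 1].

Rainfall enters multiplicatively: realized larval survival is the
hydroperiod/HIS (and density) prediction times the October–June
metamorph fraction — a continuous piecewise-linear ramp that is 0 at or
below 404.5 mm and 1 at or above 674.5 mm.  Multiplication nests the
deterministic model exactly when the ramp saturates at 1, which the test
suite exploits (saturating-rainfall PVA ≡ density-dependent model).  The
ramp's knots are shared by natives and hybrids.  The December–January
total thins breeding females through a logit-linear fraction that
composes multiplicatively with the individual breeding probability.

## Shipped synthetic coefficients

The package never hard-codes study-specific coefficients into the
algorithms; all coefficients are data.  The shipped default set (the
`ParameterDraw` field defaults) is an order-of-magnitude-realistic
parameterization chosen, using the deterministic mean-field recursion
below, to place the system in the documented qualitative regime: the
120-day all-native pond grows (mean-field λ ≈ 1.47) while the 80-day pond
declines (λ ≈ 0.70), hybrid ancestry raises larval survival and metamorph
mass, and density-dependent equilibria span ~15–3000 adults across the
scenario grid — large enough for meaningful dynamics, small enough for
fast simulation.  Key choices: adult asymptotic mass ≈ 23 g
(`growth_intercept/(1−growth_slope)`), clutch ≈ 700 eggs at that mass,
annual adult survival ≈ 0.77, larval survival at 100 d for natives
≈ 0.0016 rising ~e-fold per 10 hydroperiod days, density slope −0.7 on
ln-survival with `D_ref = 25` eggs·m⁻³.

Between-draw variation in the synthetic generator is independent per
coefficient: normal on the link scale, log-normal for strictly-positive
spreads, logit-normal for the breeding probability, clipped at zero for
the sign-constrained density slopes.  Coefficient correlations present in
a real posterior are deliberately out of scope.  Synthetic rainfall is
bivariate log-normal (medians 180 mm and 600 mm, log-SDs 0.50 and 0.35,
correlation 0.8 between windows): positive, right-skewed, with correlated
wet/dry years; roughly one year in six falls below the reproductive-failure
knot, which is what makes droughts demographically meaningful.  The
generator emulates the *structure* of real posterior draws and weather
records, not their values — passing tests demonstrate correct mechanics
and directionally correct comparative statics, not field-calibrated
absolute rates.

A maximum-likelihood + parametric-bootstrap fitter
(`fit_hydro_his_regressions`) converts raw hydroperiod-experiment rows
(hydroperiod, HIS, survival flag or metamorph mass) into coefficient
draws with the same schema, as a sampler-free stand-in for Bayesian
refitting; real posterior draws can be supplied through the same CSV.

## Scenario and experiment conventions

Scenarios follow the 5 × 5 grid (hydroperiod 80–120 d by 10; initial
hybrid proportion 0–1 by 0.25) on a 1000 m³ pond founded with 100 mature
adults.  Hybrid founders draw HIS from Beta(α, α(1−μ)/μ) with α = 10,
μ = 0.75 — a continuous beta-family version of the stated beta-binomial
(whose trial count is unstated), right-shifted with a left tail; natives
are fixed at HIS 0.05.  Founder ages are uniform on 1–5 and founder
masses normal around the growth kernel's stationary mass (the first two
transient years are excluded from λ regardless).

* λ = `exp(OLS slope of ln N_t on t)`, years 3–12 of a 12-year
  density-independent run (no cap, no density, no rainfall).  The slope is
  exponentiated: reported growth rates are yearly ratios.  Windows
  containing zero censuses regress the positive years when ≥ 5 remain,
  else record λ = 0 and flag the run extinct.
* K = median adult count over the final quarter of a 100-year
  density-dependent run (per run), with collapsed runs contributing 0;
  scenario K is the median of per-run medians.  Adults above the 100,000
  cap are removed by uniform random down-sampling (the cap's mechanism is
  a package choice; the cap itself applies to all capped modes).
* PVA resamples one historical rainfall year (uniform, with replacement)
  per simulated year; quasi-extinction below 3 post-metamorphic
  individuals is absorbing and the run stops there.
* ΔHIS = `100% × (HIS_removal − HIS_baseline)/HIS_baseline` at year 100.
  Removal happens after death removal and before breeder selection, so
  individuals removed in a year do not breed that year: a program that
  screens breeding adults at the pond and removed them after breeding
  would forfeit most of its effect in short programs.  ΔHIS is undefined
  (NaN) when either arm goes extinct or the baseline is hybrid-free.

The genotyping assay is modelled as m = round(1/detection_threshold)
diagnostic markers; a screened individual's measured HIS is k/m with
k ~ Binomial(m, true HIS), and both the detection and removal criteria
apply to the *measured* value.  This ties assay precision to the
detection threshold with a single parameter.

### Random-stream design

Every experiment derives three independent generators per
(seed, scenario, iteration): environment (rainfall resampling), demography
(all individual-level randomness), and removal (capture, screening
subset, assay noise).  Removal arms and their no-removal baseline share
the environment and demography streams and differ only in the removal
stream, so ΔHIS is a paired comparison — this reduces its Monte-Carlo
variance without changing its expectation (separate baselines would be
unbiased too, just noisier) — and a strategy with zero capture
probability reproduces the baseline trajectory exactly, which the test
suite asserts.

## Mean-field oracle

`meanfield_trajectory` iterates the *expected-value* map of the annual
cycle over age cohorts 0–15 (count, mass, mature fraction per cohort).
For a population sharing a single HIS value and kernels with zero residual
spread, the recursion is the exact expectation of the stochastic engine
up to demographic noise, because masses are then deterministic per cohort
and every nonlinearity is evaluated at the same point.  Its density-
dependent fixed point predicts simulated K (asserted within 10% over 200
century runs), and its density-independent growth ratio was the
calibration instrument for the shipped defaults.  The oracle shares only
the vital-rate functions with the engine, not the population code.

## Problem sizes and numerical choices

The shipped test suite runs the directional experiments at 8 synthetic
draws × 25 scenarios (λ, viability), 6 draws × 25 scenarios (K), 20
paired replicates for the removal sign-pattern sweep, and an 8-year
horizon (regression years 3–8) for the λ trend — sizes chosen so the full
suite completes in about a minute on one core while every comparison
retains clear signal; the CLI defaults keep the conventional 12-year λ
horizon and are intended for larger draw counts.  Masses are floored at
0.5 g wherever a kernel draw could go non-positive.  Clutch size is the
rounded fertility value, thinned binomially by larval survival (per-larva
survival semantics).  λ trend assertions use a regression slope over all
runs rather than strict per-level median ordering, since adjacent medians
can tie at small draw counts.

## Known limitations

* Coefficient draws are independent across coefficients; real posteriors
  are correlated, so propagated uncertainty bands are approximate.
* The mean-field oracle is exact only for single-HIS, zero-spread
  configurations; mixed-HIS equilibria are checked directionally, not
  against closed form.
* The removal sweep is one-factor-at-a-time around a documented center,
  not a full factorial of the five management grids.
* Effect summaries fit a random intercept per iteration (or fixed
  iteration dummies as fallback); random slopes are not modelled.
* Hydroperiod is fixed per scenario; rainfall-driven hydroperiod
  variation and climate trends are out of scope.
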