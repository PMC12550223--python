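"""The four computational experiments and their summary statistics.

* density-independent runs -> intrinsic growth rate lambda (log-linear
  regression of census size on time over years 3–12);
* density-dependent runs -> carrying capacity K (median adult count over
  years 75–100, with the 100,000-adult cap);
* population viability analysis (PVA) -> 100-year persistence under
  resampled historical rainfall with a 3-individual quasi-extinction
  threshold, plus stable size as a percent of K;
* the hybrid-removal grid -> percent change in population HIS relative to a
  paired no-removal baseline (delta-HIS; negative is management success).

Each experiment sweeps scenarios x parameter draws with three independent,
separately seeded random streams (environment, demography, removal), so a
removal arm and its baseline see identical environments and a
zero-intensity removal strategy reproduces the baseline exactly.

A deterministic mean-field (expected-value) recursion over age cohorts is
included as an independent cross-check for the stochastic engine: with
zero-residual-spread coefficients its fixed point predicts the simulated K.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError
from .params import ParameterDraw, RainfallYear, sample_rainfall_year
from .population import (
    PondScenario,
    Population,
    RemovalStrategy,
    YearRecord,
    annual_cycle,
    init_population,
)
from . import vital_rates as vr
from .vital_rates import EnvironmentYear

__all__ = [
    "SimulationResult",
    "RemovalOutcome",
    "default_scenarios",
    "estimate_lambda",
    "run_density_independent",
    "run_density_dependent",
    "run_pva",
    "percent_of_k",
    "delta_his",
    "run_removal_grid",
    "meanfield_trajectory",
    "meanfield_lambda",
    "meanfield_equilibrium",
    "results_to_frame",
]

QUASI_EXTINCTION_DEFAULT = 3

HYDROPERIOD_GRID = (80.0, 90.0, 100.0, 110.0, 120.0)
PROP_HYBRID_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class SimulationResult:
    """Outcome of one (scenario x parameter draw) run."""

    scenario: PondScenario
    iteration_id: int
    mode: str  # density_independent | density_dependent | pva | removal
    years: list[YearRecord] = field(default_factory=list, repr=False)
    lambda_hat: float | None = None
    k_hat: float | None = None
    extinct: bool = False
    n_100: int | None = None
    final_his: float | None = None
    stable_size: float | None = None


@dataclass
class RemovalOutcome:
    """Delta-HIS of one removal strategy against its paired baseline."""

    strategy: RemovalStrategy
    scenario: PondScenario
    his_with_removal: float
    his_baseline: float
    delta_his_pct: float
    removal_extinct: bool = False
    baseline_extinct: bool = False


def default_scenarios(
    hydroperiods: Sequence[float] = HYDROPERIOD_GRID,
    prop_hybrids: Sequence[float] = PROP_HYBRID_GRID,
    **overrides,
) -> list[PondScenario]:
    """The 5 x 5 hydroperiod x hybrid-proportion scenario grid."""
    return [
        PondScenario(hydroperiod_days=h, prop_hybrid=p, **overrides)
        for h in hydroperiods
        for p in prop_hybrids
    ]


def estimate_lambda(
    records: Sequence[YearRecord], first_year: int = 3, last_year: int = 12
) -> float:
    """Intrinsic growth rate from a census time series.

    lambda = exp(OLS slope of ln N_t on t) over the year window (the first
    two transient years excluded by default).  If the window contains zero
    censuses, the regression uses the positive-census years when at least
    five remain; otherwise lambda is 0 by convention (the caller flags the
    run extinct).
    """
    by_year = {r.year: r.n_total for r in records}
    years = np.array([y for y in range(first_year, last_year + 1) if y in by_year])
    if years.size < 2:
        raise ConfigurationError(
            f"records must cover years {first_year}..{last_year} (found {years.size})"
        )
    n = np.array([by_year[y] for y in years], dtype=float)
    pos = n > 0
    if not pos.all():
        if pos.sum() < 5:
            return 0.0
        years, n = years[pos], n[pos]
    slope = np.polyfit(years, np.log(n), 1)[0]
    return float(np.exp(slope))


def _streams(root_seed: int, scen_i: int, iter_i: int, arm: int = 0):
    """Three independent generators (environment, demography, removal).

    The environment and demography streams depend only on (seed, scenario,
    iteration), never on the arm, so paired removal/baseline runs share them.
    """
    def gen(code: int, with_arm: bool) -> np.random.Generator:
        key = [root_seed, scen_i, iter_i, code] + ([arm] if with_arm else [])
        return np.random.default_rng(np.random.SeedSequence(key))

    return gen(1, False), gen(2, False), gen(3, True)


def run_density_independent(
    scenarios: Sequence[PondScenario],
    draws: Sequence[ParameterDraw],
    n_years: int = 12,
    rng_seed: int = 0,
) -> list[SimulationResult]:
    """Exponential-phase runs: no density feedback, no rainfall, no cap."""
    results = []
    for scen_i, scenario in enumerate(scenarios):
        env = EnvironmentYear(hydroperiod_days=scenario.hydroperiod_days)
        for iter_i, draw in enumerate(draws):
            _, demog_rng, _ = _streams(rng_seed, scen_i, iter_i)
            pop = init_population(scenario, demog_rng, draw)
            records = []
            for year in range(1, n_years + 1):
                pop, rec = annual_cycle(
                    pop, scenario, draw, env, demog_rng, year=year,
                    density_dependent=False, capped=False,
                )
                records.append(rec)
            lam = estimate_lambda(records, 3, min(12, n_years))
            extinct = any(
                r.n_total == 0 for r in records if 3 <= r.year <= min(12, n_years)
            )
            results.append(
                SimulationResult(
                    scenario=scenario, iteration_id=draw.iteration_id,
                    mode="density_independent", years=records,
                    lambda_hat=lam, extinct=extinct,
                )
            )
    return results


def _late_window_median(records: Sequence[YearRecord], n_years: int) -> float:
    """Median adult count over years 75–100 (scaled to shorter runs)."""
    first = max(1, int(round(n_years * 0.75)))
    counts = [r.n_adults for r in records if r.year >= first]
    missing = n_years - (records[-1].year if records else 0)
    counts.extend([0] * missing)  # extinct runs contribute zeros
    return float(np.median(counts)) if counts else 0.0


def run_density_dependent(
    scenarios: Sequence[PondScenario],
    draws: Sequence[ParameterDraw],
    n_years: int = 100,
    rng_seed: int = 0,
) -> tuple[list[SimulationResult], dict[tuple[float, float], float]]:
    """Density-regulated runs; returns per-run results and scenario-level K.

    Per-run k_hat is the median adult count over the final quarter of the
    run (years 75–100 at the default length); populations that collapse
    contribute k_hat = 0.  Scenario K is the median of per-run medians.
    """
    results = []
    k_by_scenario: dict[tuple[float, float], float] = {}
    for scen_i, scenario in enumerate(scenarios):
        env = EnvironmentYear(hydroperiod_days=scenario.hydroperiod_days)
        k_hats = []
        for iter_i, draw in enumerate(draws):
            _, demog_rng, _ = _streams(rng_seed, scen_i, iter_i)
            pop = init_population(scenario, demog_rng, draw)
            records = []
            for year in range(1, n_years + 1):
                pop, rec = annual_cycle(
                    pop, scenario, draw, env, demog_rng, year=year,
                    density_dependent=True, capped=True,
                )
                records.append(rec)
                if rec.n_total == 0:
                    break
            k_hat = _late_window_median(records, n_years)
            extinct = records[-1].n_total == 0
            k_hats.append(k_hat)
            results.append(
                SimulationResult(
                    scenario=scenario, iteration_id=draw.iteration_id,
                    mode="density_dependent", years=records,
                    k_hat=k_hat, extinct=extinct,
                )
            )
        k_by_scenario[(scenario.hydroperiod_days, scenario.prop_hybrid)] = float(
            np.median(k_hats)
        )
    return results, k_by_scenario


def _run_pva_single(
    scenario: PondScenario,
    draw: ParameterDraw,
    rainfall: Sequence[RainfallYear],
    n_years: int,
    quasi_extinction: int,
    env_rng: np.random.Generator,
    demog_rng: np.random.Generator,
    strategy: RemovalStrategy | None = None,
    removal_rng: np.random.Generator | None = None,
) -> SimulationResult:
    pop = init_population(scenario, demog_rng, draw)
    records: list[YearRecord] = []
    extinct = False
    for year in range(1, n_years + 1):
        rain = sample_rainfall_year(rainfall, env_rng)
        env = EnvironmentYear(
            hydroperiod_days=scenario.hydroperiod_days,
            dec_jan_mm=rain.dec_jan_mm,
            oct_jun_mm=rain.oct_jun_mm,
        )
        pop, rec = annual_cycle(
            pop, scenario, draw, env, demog_rng,
            strategy=strategy, removal_rng=removal_rng, year=year,
            density_dependent=True, capped=True,
        )
        rec.rainfall_year_id = rain.year_id
        records.append(rec)
        if rec.n_total < quasi_extinction:
            extinct = True  # quasi-extinction is absorbing
            break
    result = SimulationResult(
        scenario=scenario, iteration_id=draw.iteration_id,
        mode="removal" if strategy is not None else "pva",
        years=records, extinct=extinct,
    )
    result.n_100 = 0 if extinct else records[-1].n_total
    result.final_his = float("nan") if extinct else records[-1].mean_his
    result.stable_size = 0.0 if extinct else _late_window_median(records, n_years)
    return result


def run_pva(
    scenarios: Sequence[PondScenario],
    draws: Sequence[ParameterDraw],
    rainfall: Sequence[RainfallYear],
    n_years: int = 100,
    quasi_extinction: int = QUASI_EXTINCTION_DEFAULT,
    rng_seed: int = 0,
) -> list[SimulationResult]:
    """Stochastic 100-year viability runs with resampled historical rainfall."""
    if len(rainfall) == 0:
        raise ConfigurationError("rainfall series must be non-empty")
    results = []
    for scen_i, scenario in enumerate(scenarios):
        for iter_i, draw in enumerate(draws):
            env_rng, demog_rng, _ = _streams(rng_seed, scen_i, iter_i)
            results.append(
                _run_pva_single(
                    scenario, draw, rainfall, n_years, quasi_extinction,
                    env_rng, demog_rng,
                )
            )
    return results


def percent_of_k(stable_size: float, k: float) -> float:
    """Stable PVA population size as a percentage of carrying capacity."""
    if k <= 0:
        raise ConfigurationError("percent_of_k undefined for k <= 0")
    return 100.0 * stable_size / k


def delta_his(his_with_removal: float, his_baseline: float) -> float:
    """Percent change in population HIS under removal; negative = beneficial."""
    if his_baseline <= 0:
        raise ConfigurationError("delta_his undefined for a hybrid-free baseline")
    return 100.0 * (his_with_removal - his_baseline) / his_baseline


def run_removal_grid(
    strategy_grid: Sequence[RemovalStrategy],
    scenarios: Sequence[PondScenario],
    draw: ParameterDraw,
    rainfall: Sequence[RainfallYear],
    rng_seed: int = 0,
    n_years: int = 100,
    quasi_extinction: int = QUASI_EXTINCTION_DEFAULT,
) -> tuple[list[RemovalOutcome], list[SimulationResult]]:
    """Delta-HIS for every strategy x scenario, against paired baselines.

    Uses one parameter draw (conventionally the coefficient-wise posterior
    mean).  Each scenario gets one no-removal baseline sharing the
    environment and demography streams of its removal arms, so delta-HIS
    differences are attributable to the removal action alone.
    """
    for scenario in scenarios:
        if scenario.prop_hybrid <= 0:
            raise ConfigurationError(
                "removal scenarios require prop_hybrid > 0 (baseline HIS would be trivial)"
            )
    outcomes: list[RemovalOutcome] = []
    baselines: list[SimulationResult] = []
    for scen_i, scenario in enumerate(scenarios):
        env_rng, demog_rng, _ = _streams(rng_seed, scen_i, 0)
        baseline = _run_pva_single(
            scenario, draw, rainfall, n_years, quasi_extinction, env_rng, demog_rng,
        )
        baselines.append(baseline)
        for strat_i, strategy in enumerate(strategy_grid):
            env_rng, demog_rng, removal_rng = _streams(rng_seed, scen_i, 0, arm=strat_i + 1)
            arm = _run_pva_single(
                scenario, draw, rainfall, n_years, quasi_extinction,
                env_rng, demog_rng, strategy=strategy, removal_rng=removal_rng,
            )
            his_b = baseline.final_his
            his_r = arm.final_his
            if baseline.extinct or arm.extinct or not his_b or np.isnan(his_b):
                d = float("nan")
            else:
                d = delta_his(his_r, his_b)
            outcomes.append(
                RemovalOutcome(
                    strategy=strategy, scenario=scenario,
                    his_with_removal=his_r if his_r is not None else float("nan"),
                    his_baseline=his_b if his_b is not None else float("nan"),
                    delta_his_pct=d,
                    removal_extinct=arm.extinct, baseline_extinct=baseline.extinct,
                )
            )
    return outcomes, baselines


# ---------------------------------------------------------------------------
# Deterministic mean-field recursion (independent oracle for the engine)
# ---------------------------------------------------------------------------

def _meanfield_step(
    n: np.ndarray, mass: np.ndarray, pmat: np.ndarray,
    draw: ParameterDraw, scenario: PondScenario,
    density_dependent: bool, his0: float,
    breed_frac: float = 1.0, rain_metamorph_frac: float = 1.0,
):
    """One expected-value year over age cohorts 0..15."""
    # age shift; the cohort leaving age 15 dies by the age rule
    n = np.concatenate([[0.0], n[:-1]])
    mass = np.concatenate([[vr.MASS_FLOOR_G], mass[:-1]])
    pmat = np.concatenate([[0.0], pmat[:-1]])

    occupied = n > 0
    s = np.zeros_like(n)
    s[occupied] = expit(
        draw.surv_intercept + draw.surv_mass_slope * (mass[occupied] - draw.mass_center)
    )
    n = n * s
    mass = np.maximum(draw.growth_intercept + draw.growth_slope * mass, vr.MASS_FLOOR_G)
    p_new = expit(draw.maturity_intercept + draw.maturity_mass_slope * (mass - draw.mass_center))
    pmat = pmat + (1.0 - pmat) * p_new

    fert = np.maximum(0.0, draw.fert_intercept + draw.fert_mass_slope * mass)
    females = 0.5 * n * pmat * draw.breeding_prob * breed_frac
    eggs = float(np.sum(females * fert))

    surv = vr.larval_survival(scenario.hydroperiod_days, his0, draw)
    mean_mass0 = (
        draw.meta_intercept
        + draw.meta_hydro_slope * (scenario.hydroperiod_days - draw.hydro_center)
        + draw.meta_his_slope * his0
    )
    if density_dependent:
        egg_density = eggs / scenario.volume_m3
        surv = vr.density_adjusted_survival(surv, egg_density, draw)
        mean_mass0 = vr.density_adjusted_mass(max(mean_mass0, vr.MASS_FLOOR_G), egg_density, draw)
    surv *= rain_metamorph_frac

    n[0] = eggs * surv
    mass[0] = max(mean_mass0, vr.MASS_FLOOR_G)
    pmat[0] = 0.0
    return n, mass, pmat


def meanfield_trajectory(
    draw: ParameterDraw,
    scenario: PondScenario,
    n_years: int,
    density_dependent: bool = True,
    his0: float | None = None,
) -> pd.DataFrame:
    """Expected-value trajectory over age cohorts (no demographic noise).

    Exact for a population whose individuals share one HIS value and whose
    kernels have zero residual spread; used as the independent cross-check
    of the stochastic engine.  Returns per-year total and adult counts.
    """
    if his0 is None:
        his0 = (
            scenario.native_his
            if scenario.prop_hybrid == 0
            else scenario.prop_hybrid * scenario.hybrid_his_mu
            + (1 - scenario.prop_hybrid) * scenario.native_his
        )
    n_ages = vr.MAX_AGE_YEARS + 1
    n = np.zeros(n_ages)
    mass = np.full(n_ages, draw.stationary_mass())
    pmat = np.zeros(n_ages)
    n[1:6] = scenario.init_n / 5.0
    pmat[1:6] = 1.0

    rows = []
    for year in range(1, n_years + 1):
        n, mass, pmat = _meanfield_step(
            n, mass, pmat, draw, scenario, density_dependent, his0
        )
        rows.append(
            {"year": year, "n_total": float(n.sum()), "n_adults": float((n * pmat).sum())}
        )
    return pd.DataFrame(rows)


def meanfield_lambda(draw: ParameterDraw, scenario: PondScenario, n_years: int = 40) -> float:
    """Asymptotic yearly growth ratio of the density-independent recursion."""
    traj = meanfield_trajectory(draw, scenario, n_years, density_dependent=False)
    tail = traj["n_total"].to_numpy()
    if tail[-2] <= 0:
        return 0.0
    return float(tail[-1] / tail[-2])


def meanfield_equilibrium(
    draw: ParameterDraw, scenario: PondScenario, n_years: int = 400
) -> float:
    """Adult-count fixed point of the density-dependent recursion (0 = collapse)."""
    traj = meanfield_trajectory(draw, scenario, n_years, density_dependent=True)
    adults = traj["n_adults"].to_numpy()
    if adults[-1] < 1.0:
        return 0.0
    return float(np.median(adults[int(0.75 * n_years):]))


def results_to_frame(results: Iterable[SimulationResult]) -> pd.DataFrame:
    """Flatten simulation results into the per-run results table."""
    rows = []
    for r in results:
        rows.append(
            {
                "mode": r.mode,
                "hydroperiod_days": r.scenario.hydroperiod_days,
                "prop_hybrid": r.scenario.prop_hybrid,
                "volume_m3": r.scenario.volume_m3,
                "init_n": r.scenario.init_n,
                "iteration_id": r.iteration_id,
                "lambda_hat": r.lambda_hat,
                "k_hat": r.k_hat,
                "n_100": r.n_100,
                "stable_size": r.stable_size,
                "final_his": r.final_his,
                "extinct": r.extinct,
            }
        )
    return pd.DataFrame(rows)
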