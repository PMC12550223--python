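import dataclasses
import math

import numpy as np
import pytest
from scipy.stats import binom

from pondipm import (
    ConfigurationError,
    EnvironmentYear,
    Individual,
    ParameterDraw,
    PondScenario,
    Population,
    RemovalStrategy,
    annual_cycle,
    apply_removal,
    init_population,
    make_offspring,
    pair_breeders,
)
from pondipm.population import SEX_FEMALE, SEX_MALE


def _pop(sex, age, mass, his, mature):
    n = len(sex)
    return Population(np.arange(n), sex, age, mass, his, mature)


class TestInitPopulation:
    def test_hybrid_and_native_counts(self, rng, draw):
        scen = PondScenario(init_n=100, prop_hybrid=0.25)
        pop = init_population(scen, rng, draw)
        n_hybrid = int(np.sum(pop.his != scen.native_his))
        assert pop.size == 100
        assert n_hybrid == 25
        assert pop.n_adults == 100

    def test_all_native_his_is_fixed(self, rng, draw):
        pop = init_population(PondScenario(init_n=50, prop_hybrid=0.0), rng, draw)
        assert np.all(pop.his == 0.05)

    def test_hybrid_his_mean_matches_beta_construction(self, draw):
        # Beta(alpha, alpha(1-mu)/mu) has mean mu = 0.75
        rng = np.random.default_rng(7)
        scen = PondScenario(init_n=10_000, prop_hybrid=1.0)
        pop = init_population(scen, rng, draw)
        alpha, mu = scen.hybrid_his_alpha, scen.hybrid_his_mu
        beta = alpha * (1 - mu) / mu
        sd = math.sqrt(alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1)))
        assert abs(pop.his.mean() - mu) < 3 * sd / math.sqrt(10_000)

    def test_empty_population_is_valid(self, rng, draw):
        pop = init_population(PondScenario(init_n=0), rng, draw)
        assert pop.size == 0


class TestPairBreeders:
    def test_single_male_mates_all_females(self, rng):
        pairs = pair_breeders(np.array([0, 1, 2]), np.array([7]), rng)
        assert pairs.shape == (3, 2)
        assert np.all(pairs[:, 1] == 7)

    def test_no_females_no_pairs(self, rng):
        assert pair_breeders(np.array([]), np.array([1, 2, 3, 4, 5]), rng).shape == (0, 2)

    def test_uniform_mate_assignment(self):
        rng = np.random.default_rng(3)
        pairs = pair_breeders(np.arange(1000), np.array([10_001, 10_002]), rng)
        count = int(np.sum(pairs[:, 1] == 10_001))
        assert abs(count - 500) < 3 * math.sqrt(1000 * 0.25)


class TestMakeOffspring:
    def _parents(self, mother_mass=20.0, mother_his=0.05, father_his=1.0):
        mother = Individual(id=1, sex=SEX_FEMALE, age_years=4, mass_g=mother_mass,
                            his=mother_his, mature=True)
        father = Individual(id=2, sex=SEX_MALE, age_years=4, mass_g=18.0,
                            his=father_his, mature=True)
        return mother, father

    def test_zero_larval_survival_means_no_offspring(self, rng, draw):
        lethal = dataclasses.replace(draw, larv_intercept=-60.0)
        env = EnvironmentYear(hydroperiod_days=100.0)
        kids = make_offspring(self._parents(), PondScenario(), lethal, env, rng)
        assert kids == []

    def test_certain_survival_yields_full_identical_clutch(self, rng):
        d = dataclasses.replace(
            ParameterDraw(), fert_intercept=0.0, fert_mass_slope=5.0,
            larv_intercept=60.0, meta_sd=0.0,
        )
        env = EnvironmentYear(hydroperiod_days=100.0)
        kids = make_offspring(self._parents(mother_mass=20.0), PondScenario(), d, env, rng)
        assert len(kids) == 100  # clutch = round(5 * 20)
        masses = {k.mass_g for k in kids}
        assert len(masses) == 1
        assert all(k.age_years == 0 and not k.mature for k in kids)

    def test_binomial_recruitment_mean(self, draw):
        rng = np.random.default_rng(5)
        d = dataclasses.replace(
            draw, fert_intercept=0.0, fert_mass_slope=50.0,
            larv_intercept=draw.larv_intercept,
        )
        env = EnvironmentYear(hydroperiod_days=120.0)
        from pondipm.vital_rates import larval_survival

        p = larval_survival(120.0, 0.525, d)
        counts = [
            len(make_offspring(self._parents(mother_mass=20.0), PondScenario(), d, env, rng))
            for _ in range(1000)
        ]
        clutch = 1000
        se = math.sqrt(clutch * p * (1 - p) / 1000)
        assert abs(np.mean(counts) - clutch * p) < 3 * se

    def test_offspring_his_is_mid_parent(self, rng, draw):
        d = dataclasses.replace(draw, larv_intercept=60.0, fert_intercept=0.0, fert_mass_slope=1.0)
        env = EnvironmentYear(hydroperiod_days=100.0)
        kids = make_offspring(self._parents(mother_his=0.05, father_his=1.0),
                              PondScenario(), d, env, rng)
        assert kids and all(k.his == pytest.approx(0.525) for k in kids)


class TestAnnualCycle:
    def test_no_males_means_no_offspring(self, rng, draw, native_scenario):
        n = 30
        pop = _pop([SEX_FEMALE] * n, [3] * n, [20.0] * n, [0.05] * n, [True] * n)
        env = EnvironmentYear(hydroperiod_days=120.0)
        d = dataclasses.replace(draw, breeding_prob=1.0)
        _, rec = annual_cycle(pop, native_scenario, d, env, rng)
        assert rec.n_metamorphs == 0

    def test_mid_parent_his_with_two_parents(self, rng, draw):
        d = dataclasses.replace(draw, breeding_prob=1.0, larv_intercept=60.0)
        pop = _pop([SEX_FEMALE, SEX_MALE], [3, 3], [20.0, 20.0], [0.05, 1.0], [True, True])
        env = EnvironmentYear(hydroperiod_days=120.0)
        new_pop, rec = annual_cycle(pop, PondScenario(prop_hybrid=0.5), d, env, rng)
        offspring_his = new_pop.his[new_pop.age == 0]
        assert rec.n_metamorphs > 0
        assert np.all(offspring_his == pytest.approx(0.525))

    def test_adult_cap_enforced_exactly(self, rng, draw):
        n = 80
        pop = _pop([SEX_FEMALE] * 40 + [SEX_MALE] * 40, [3] * n, [20.0] * n,
                   [0.05] * n, [True] * n)
        scen = PondScenario(adult_cap=50)
        env = EnvironmentYear(hydroperiod_days=120.0)
        immortal = dataclasses.replace(draw, surv_intercept=60.0, larv_intercept=-60.0)
        new_pop, rec = annual_cycle(pop, scen, immortal, env, rng, capped=True,
                                    density_dependent=True)
        assert rec.n_adults == 50

    def test_age_sixteen_rule_kills(self, rng, draw):
        # a 15-year-old turns 16 during the cycle and must die
        pop = _pop([SEX_MALE], [15], [25.0], [0.05], [True])
        immortal = dataclasses.replace(draw, surv_intercept=60.0)
        env = EnvironmentYear(hydroperiod_days=120.0)
        _, rec = annual_cycle(pop, PondScenario(), immortal, env, rng)
        assert rec.n_total == 0

    def test_maturity_is_absorbing(self, draw):
        rng = np.random.default_rng(0)
        n = 200
        pop = _pop([SEX_MALE] * n, [3] * n, [25.0] * n, [0.05] * n, [True] * n)
        never_mature = dataclasses.replace(draw, maturity_intercept=-60.0,
                                           surv_intercept=60.0, larv_intercept=-60.0)
        env = EnvironmentYear(hydroperiod_days=120.0)
        new_pop, _ = annual_cycle(pop, PondScenario(), never_mature, env, rng)
        assert np.all(new_pop.mature)

    def test_all_native_population_keeps_constant_his(self, rng, draw, native_scenario):
        pop = init_population(dataclasses.replace(native_scenario, init_n=60), rng, draw)
        env = EnvironmentYear(hydroperiod_days=110.0)
        for year in range(1, 21):
            pop, rec = annual_cycle(pop, native_scenario, draw, env, rng, year=year)
            if rec.n_total:
                assert rec.mean_his == pytest.approx(0.05)

    def test_egg_density_in_density_independent_mode_rejected(self, rng, draw, native_scenario):
        pop = init_population(native_scenario, rng, draw)
        env = EnvironmentYear(hydroperiod_days=110.0, egg_density=10.0)
        with pytest.raises(ConfigurationError, match="mode"):
            annual_cycle(pop, native_scenario, draw, env, rng, density_dependent=False)

    def test_his_convexity_over_full_run(self, draw):
        """Mid-parent inheritance keeps every HIS within the founding range."""
        rng = np.random.default_rng(42)
        scen = PondScenario(hydroperiod_days=110.0, prop_hybrid=0.5, init_n=100)
        pop = init_population(scen, rng, draw)
        lo, hi = pop.his.min(), pop.his.max()
        env = EnvironmentYear(hydroperiod_days=110.0)
        for year in range(1, 101):
            pop, _ = annual_cycle(pop, scen, draw, env, rng, year=year,
                                  density_dependent=True, capped=True)
            if pop.size == 0:
                break
            assert pop.his.min() >= lo - 1e-12
            assert pop.his.max() <= hi + 1e-12


class TestApplyRemoval:
    def _adults(self, his):
        n = len(his)
        return _pop([SEX_MALE] * n, [4] * n, [20.0] * n, his, [True] * n)

    def test_zero_capture_probability_removes_nobody(self, rng):
        pop = self._adults([0.8] * 20)
        strat = RemovalStrategy(p_capture=0.0)
        new_pop, n = apply_removal(pop, strat, rng)
        assert n == 0 and new_pop.size == 20

    def test_zero_screening_budget_removes_nobody(self, rng):
        pop = self._adults([0.9] * 20)
        strat = RemovalStrategy(max_screened=0, p_capture=1.0)
        _, n = apply_removal(pop, strat, rng)
        assert n == 0

    def test_screening_respects_budget(self):
        rng = np.random.default_rng(1)
        pop = self._adults([0.99] * 100)
        strat = RemovalStrategy(p_capture=1.0, max_screened=10,
                                detection_threshold=0.05, his_removal_threshold=0.1)
        _, n = apply_removal(pop, strat, rng)
        assert n <= 10

    def test_measured_his_binomial_tails(self):
        """Detection is binomial in the marker count m = round(1/threshold).

        With m = 20 markers and removal iff measured HIS >= 0.05 and > 0.1
        (i.e. >= 3 successes), removal probabilities are the exact binomial
        tails: ~0.9996 for true HIS 0.8 and ~0.0755 for true HIS 0.05.
        """
        strat = RemovalStrategy(p_capture=1.0, max_screened=1000,
                                detection_threshold=0.05, his_removal_threshold=0.1)
        assert strat.n_markers == 20
        n_rep = 2000
        removed_high = removed_low = 0
        rng = np.random.default_rng(21)
        for _ in range(n_rep):
            pop = self._adults([0.05, 0.8])
            new_pop, n = apply_removal(pop, strat, rng)
            removed_high += 0.8 not in new_pop.his
            removed_low += 0.05 not in new_pop.his
        p_high = 1 - binom.cdf(2, 20, 0.8)   # ~0.99998
        p_low = 1 - binom.cdf(2, 20, 0.05)   # ~0.0755
        assert removed_high / n_rep > 0.999
        se_low = math.sqrt(p_low * (1 - p_low) / n_rep)
        assert abs(removed_low / n_rep - p_low) < 4 * se_low

    def test_invalid_detection_threshold_rejected(self):
        with pytest.raises(ConfigurationError):
            RemovalStrategy(detection_threshold=0.0).validate()
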