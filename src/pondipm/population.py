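"""Individual-based population engine: the 13-step annual cycle.

The population is stored column-wise (numpy arrays for sex, age, mass, HIS,
maturity) so a full year of demography — survival with the age-16 rule,
growth, maturation, fertility, breeding, death removal, optional hybrid
removal, breeder selection with optional rainfall thinning, random mate
pairing, larval survival (optionally density- and rainfall-adjusted),
binomial recruitment, and metamorph creation with mid-parent HIS — runs as
vectorized array operations.  A scalar :class:`Individual` view exists for
inspection and small-scale tests.

Randomness is split across streams by the caller: one generator drives
demography, a second (optional) drives the removal action, and environment
sampling happens outside this module entirely.  That separation lets a
removal arm and its no-removal baseline share identical environments and
makes a zero-intensity removal strategy reproduce the baseline trajectory
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .params import ParameterDraw
from . import vital_rates as vr
from .vital_rates import EnvironmentYear

__all__ = [
    "SEX_FEMALE",
    "SEX_MALE",
    "Individual",
    "Population",
    "PondScenario",
    "RemovalStrategy",
    "YearRecord",
    "init_population",
    "annual_cycle",
    "pair_breeders",
    "make_offspring",
    "apply_removal",
]

SEX_FEMALE = 0
SEX_MALE = 1


@dataclass
class Individual:
    """Scalar view of one salamander (living individuals only are tracked)."""

    id: int
    sex: int  # SEX_FEMALE or SEX_MALE
    age_years: int
    mass_g: float
    his: float  # proportion of genome of non-native ancestry, in [0, 1]
    mature: bool
    alive: bool = True


class Population:
    """Column-wise container of living individuals."""

    __slots__ = ("ids", "sex", "age", "mass", "his", "mature", "_next_id")

    def __init__(self, ids, sex, age, mass, his, mature, next_id=None):
        self.ids = np.asarray(ids, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=np.int8)
        self.age = np.asarray(age, dtype=np.int64)
        self.mass = np.asarray(mass, dtype=float)
        self.his = np.asarray(his, dtype=float)
        self.mature = np.asarray(mature, dtype=bool)
        self._next_id = int(next_id if next_id is not None else (self.ids.max() + 1 if self.size else 0))

    @classmethod
    def empty(cls) -> "Population":
        z = np.empty(0)
        return cls(z, z, z, z, z, z, next_id=0)

    @property
    def size(self) -> int:
        return self.ids.shape[0]

    @property
    def n_adults(self) -> int:
        return int(self.mature.sum())

    def mean_his(self) -> float:
        return float(self.his.mean()) if self.size else float("nan")

    def subset(self, keep: np.ndarray) -> "Population":
        return Population(
            self.ids[keep], self.sex[keep], self.age[keep], self.mass[keep],
            self.his[keep], self.mature[keep], next_id=self._next_id,
        )

    def individuals(self) -> list[Individual]:
        return [
            Individual(
                id=int(self.ids[i]), sex=int(self.sex[i]), age_years=int(self.age[i]),
                mass_g=float(self.mass[i]), his=float(self.his[i]), mature=bool(self.mature[i]),
            )
            for i in range(self.size)
        ]

    def copy(self) -> "Population":
        return Population(
            self.ids.copy(), self.sex.copy(), self.age.copy(), self.mass.copy(),
            self.his.copy(), self.mature.copy(), next_id=self._next_id,
        )


@dataclass(frozen=True)
class PondScenario:
    """One pond configuration: hydrology, size, and initial genetic composition."""

    hydroperiod_days: float = 120.0
    volume_m3: float = 1000.0
    init_n: int = 100
    prop_hybrid: float = 0.0
    native_his: float = 0.05
    hybrid_his_alpha: float = 10.0
    hybrid_his_mu: float = 0.75
    adult_cap: int = 100_000

    def validate(self) -> None:
        if self.hydroperiod_days <= 0 or self.volume_m3 <= 0:
            raise ConfigurationError("hydroperiod_days and volume_m3 must be > 0")
        if self.init_n < 0:
            raise ConfigurationError(f"init_n must be >= 0, got {self.init_n}")
        if not 0.0 <= self.prop_hybrid <= 1.0:
            raise ConfigurationError(f"prop_hybrid must be in [0, 1], got {self.prop_hybrid}")
        if not 0.0 <= self.native_his <= 1.0:
            raise ConfigurationError("native_his must be in [0, 1]")
        if not 0.0 < self.hybrid_his_mu < 1.0 or self.hybrid_his_alpha <= 0:
            raise ConfigurationError("hybrid HIS distribution requires alpha > 0, mu in (0, 1)")
        if self.adult_cap < 1:
            raise ConfigurationError("adult_cap must be >= 1")

    def label(self) -> str:
        return f"h{self.hydroperiod_days:g}_p{self.prop_hybrid:g}"


@dataclass(frozen=True)
class RemovalStrategy:
    """The five management levers of a hybrid-removal program.

    ``detection_threshold`` is the smallest HIS the genotyping assay can
    call hybrid; it implies a marker count m = round(1 / threshold), and the
    assay reports a measured HIS of k/m with k binomial in the true HIS.
    An individual is removed iff its *measured* HIS reaches the detection
    threshold and exceeds ``his_removal_threshold``.
    """

    detection_threshold: float = 0.05
    p_capture: float = 0.75
    max_screened: int = 100
    n_removal_years: int = 20
    his_removal_threshold: float = 0.5

    def validate(self) -> None:
        if not 0.0 < self.detection_threshold <= 1.0:
            raise ConfigurationError(
                f"detection_threshold must be in (0, 1], got {self.detection_threshold}"
            )
        if not 0.0 <= self.p_capture <= 1.0:
            raise ConfigurationError(f"p_capture must be in [0, 1], got {self.p_capture}")
        if self.max_screened < 0 or self.n_removal_years < 0:
            raise ConfigurationError("max_screened and n_removal_years must be >= 0")
        if not 0.0 < self.his_removal_threshold < 1.0:
            raise ConfigurationError(
                f"his_removal_threshold must be in (0, 1), got {self.his_removal_threshold}"
            )

    @property
    def n_markers(self) -> int:
        return max(1, round(1.0 / self.detection_threshold))


@dataclass
class YearRecord:
    """Census of one simulated year, taken after the full annual cycle."""

    year: int
    n_total: int
    n_adults: int
    n_metamorphs: int
    mean_his: float
    n_removed: int = 0
    rainfall_year_id: int | None = None


def init_population(
    scenario: PondScenario,
    rng: np.random.Generator,
    draw: ParameterDraw | None = None,
) -> Population:
    """Found a pond with ``init_n`` mature adults.

    ``round(prop_hybrid * init_n)`` founders are hybrids with HIS drawn from
    Beta(alpha, alpha*(1-mu)/mu) — mean ``mu`` (default 0.75), right-shifted
    with a left tail; the rest are natives at the fixed native HIS (default
    0.05).  Sexes are independent fair coin flips; ages uniform on 1..5;
    masses normal around the growth kernel's stationary mass.
    """
    scenario.validate()
    if draw is None:
        draw = ParameterDraw()
    n = scenario.init_n
    if n == 0:
        return Population.empty()

    n_hybrid = round(scenario.prop_hybrid * n)
    alpha = scenario.hybrid_his_alpha
    beta = alpha * (1.0 - scenario.hybrid_his_mu) / scenario.hybrid_his_mu
    his = np.full(n, scenario.native_his, dtype=float)
    if n_hybrid:
        his[:n_hybrid] = rng.beta(alpha, beta, size=n_hybrid)

    sex = rng.integers(0, 2, size=n).astype(np.int8)
    age = rng.integers(1, 6, size=n)
    mass = np.maximum(
        rng.normal(draw.stationary_mass(), draw.growth_sd if draw.growth_sd > 0 else 0.0, size=n)
        if draw.growth_sd > 0
        else np.full(n, draw.stationary_mass()),
        vr.MASS_FLOOR_G,
    )
    return Population(
        ids=np.arange(n), sex=sex, age=age, mass=mass, his=his,
        mature=np.ones(n, dtype=bool), next_id=n,
    )


def pair_breeders(
    females: np.ndarray, males: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Assign each breeding female one male uniformly at random, with replacement.

    Returns an array of (female, male) index pairs, shape (n_females, 2);
    empty if either sex is absent.  Males may appear in several pairs.
    """
    females = np.asarray(females)
    males = np.asarray(males)
    if females.size == 0 or males.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    mates = males[rng.integers(0, males.size, size=females.size)]
    return np.column_stack([females, mates]).astype(np.int64)


def _spawn_metamorphs(
    clutch: np.ndarray,
    off_his: np.ndarray,
    scenario: PondScenario,
    draw: ParameterDraw,
    env: EnvironmentYear,
    rng: np.random.Generator,
    density_dependent: bool,
):
    """Shared recruitment core: per-pair clutches -> surviving metamorphs.

    Returns (sex, mass, his) arrays for the recruits plus the realized egg
    density (None in density-independent mode).
    """
    base_s = vr.larval_survival(env.hydroperiod_days, off_his, draw)
    base_s = np.atleast_1d(np.asarray(base_s, dtype=float))

    egg_density = None
    if density_dependent:
        egg_density = env.egg_density
        if egg_density is None:
            egg_density = float(clutch.sum()) / scenario.volume_m3
        surv = vr.density_adjusted_survival(base_s, egg_density, draw)
        surv = np.atleast_1d(np.asarray(surv, dtype=float))
    else:
        surv = base_s

    if env.oct_jun_mm is not None:
        surv = surv * vr.metamorph_fraction_from_rainfall(env.oct_jun_mm)

    n_off = rng.binomial(clutch, surv)
    total = int(n_off.sum())
    if total == 0:
        z = np.empty(0)
        return z.astype(np.int8), z, z, egg_density

    his_new = np.repeat(off_his, n_off)
    mean_mass = (
        draw.meta_intercept
        + draw.meta_hydro_slope * (env.hydroperiod_days - draw.hydro_center)
        + draw.meta_his_slope * his_new
    )
    if density_dependent:
        mean_mass = vr.density_adjusted_mass(np.maximum(mean_mass, vr.MASS_FLOOR_G), egg_density, draw)
    noise = rng.normal(0.0, draw.meta_sd, size=total) if draw.meta_sd > 0 else 0.0
    mass_new = np.maximum(np.atleast_1d(mean_mass + noise), vr.MASS_FLOOR_G)
    sex_new = rng.integers(0, 2, size=total).astype(np.int8)
    return sex_new, mass_new, his_new, egg_density


def make_offspring(
    pair: tuple[Individual, Individual],
    scenario: PondScenario,
    draw: ParameterDraw,
    env: EnvironmentYear,
    rng: np.random.Generator,
    density_dependent: bool = False,
) -> list[Individual]:
    """Metamorphs produced by one (female, male) pair this year.

    Clutch size is the rounded fertility of the mother; survivors are a
    binomial draw at the realized larval survival; each survivor receives
    the mid-parent HIS, age 0, a random sex, and a metamorph-mass draw.
    """
    mother, father = pair
    clutch = np.array([int(round(vr.fertility(mother.mass_g, draw)))])
    off_his = np.array([(mother.his + father.his) / 2.0])
    sex, mass, his, _ = _spawn_metamorphs(
        clutch, off_his, scenario, draw, env, rng, density_dependent
    )
    return [
        Individual(id=-1, sex=int(sex[i]), age_years=0, mass_g=float(mass[i]),
                   his=float(his[i]), mature=False)
        for i in range(len(mass))
    ]


def apply_removal(
    pop: Population, strategy: RemovalStrategy, rng: np.random.Generator
) -> tuple[Population, int]:
    """Screen and remove hybrid adults according to the management strategy.

    Every living mature adult is captured independently with probability
    ``p_capture``; among the captured, a uniform random subset of at most
    ``max_screened`` is genotyped.  The assay measures HIS as k/m for
    m = round(1/detection_threshold) markers with k ~ Binomial(m, true HIS);
    an individual is removed iff measured HIS >= detection_threshold and
    measured HIS > his_removal_threshold.
    """
    strategy.validate()
    adults = np.flatnonzero(pop.mature)
    if adults.size == 0 or strategy.max_screened == 0 or strategy.p_capture == 0.0:
        return pop, 0

    captured = adults[rng.random(adults.size) < strategy.p_capture]
    if captured.size == 0:
        return pop, 0
    if captured.size > strategy.max_screened:
        screened = rng.choice(captured, size=strategy.max_screened, replace=False)
    else:
        screened = captured

    m = strategy.n_markers
    measured = rng.binomial(m, pop.his[screened]) / m
    removed = screened[
        (measured >= strategy.detection_threshold)
        & (measured > strategy.his_removal_threshold)
    ]
    if removed.size == 0:
        return pop, 0
    keep = np.ones(pop.size, dtype=bool)
    keep[removed] = False
    return pop.subset(keep), int(removed.size)


def annual_cycle(
    pop: Population,
    scenario: PondScenario,
    draw: ParameterDraw,
    env: EnvironmentYear,
    rng: np.random.Generator,
    *,
    strategy: RemovalStrategy | None = None,
    removal_rng: np.random.Generator | None = None,
    year: int = 1,
    density_dependent: bool = False,
    capped: bool = False,
) -> tuple[Population, YearRecord]:
    """Advance the population one year through the full annual cycle.

    Step order: age increment and survival (age-16 kill rule) -> growth ->
    maturation (absorbing) -> fertility -> breeding status -> death removal
    -> hybrid removal (if a strategy is given and ``year`` is within its
    program length; removed adults do not breed that year) -> breeder
    selection (with rainfall thinning of females when ``env.dec_jan_mm`` is
    set) -> random pairing -> larval survival (density-adjusted when
    ``density_dependent``, rainfall-adjusted when ``env.oct_jun_mm`` is set)
    -> binomial recruitment -> metamorph creation (mid-parent HIS,
    density-adjusted mass) -> adult cap enforcement (capped modes only).
    """
    env.validate()
    if env.egg_density is not None and not density_dependent:
        raise ConfigurationError(
            "egg_density supplied in density-independent mode (inconsistent mode flags)"
        )
    if strategy is not None and removal_rng is None:
        raise ConfigurationError("a removal strategy requires its own removal_rng stream")

    n_removed = 0

    if pop.size == 0:
        record = YearRecord(year=year, n_total=0, n_adults=0, n_metamorphs=0,
                            mean_his=float("nan"))
        return pop, record

    # steps 1-2: age, survival (with age-16 rule), growth
    age = pop.age + 1
    p_surv = vr.post_metamorphic_survival(pop.mass, age, draw)
    alive = rng.random(pop.size) < p_surv
    mass = vr.grow(pop.mass, draw, rng)
    mass = np.atleast_1d(np.asarray(mass, dtype=float))

    # step 3: maturation, absorbing
    p_mat = vr.maturation_probability(mass, draw)
    newly_mature = (~pop.mature) & (rng.random(pop.size) < p_mat)
    mature = pop.mature | newly_mature

    # steps 4-5: fertility and breeding status
    fert = vr.fertility(mass, draw)
    breeding = rng.random(pop.size) < draw.breeding_prob

    # step 6: remove the dead
    pop = Population(pop.ids[alive], pop.sex[alive], age[alive], mass[alive],
                     pop.his[alive], mature[alive], next_id=pop._next_id)
    fert = np.atleast_1d(fert)[alive]
    breeding = breeding[alive]

    # hybrid removal acts on surviving adults, before breeder selection/pairing
    if strategy is not None and year <= strategy.n_removal_years:
        pop2, n_removed = apply_removal(pop, strategy, removal_rng)
        if n_removed:
            kept = np.isin(pop.ids, pop2.ids)
            fert = fert[kept]
            breeding = breeding[kept]
            pop = pop2

    # step 7: breeder selection, with rainfall thinning of females
    breeders = pop.mature & breeding
    is_female = pop.sex == SEX_FEMALE
    female_idx = np.flatnonzero(breeders & is_female)
    if env.dec_jan_mm is not None and female_idx.size:
        frac = vr.breeding_fraction_from_rainfall(env.dec_jan_mm, draw)
        female_idx = female_idx[rng.random(female_idx.size) < frac]
    male_idx = np.flatnonzero(breeders & ~is_female)

    # steps 8-13: pairing and recruitment
    n_metamorphs = 0
    recruits = None
    if female_idx.size and male_idx.size:
        pairs = pair_breeders(female_idx, male_idx, rng)
        mothers = pairs[:, 0]
        fathers = pairs[:, 1]
        clutch = np.rint(fert[mothers]).astype(np.int64)
        off_his = (pop.his[mothers] + pop.his[fathers]) / 2.0
        sex_new, mass_new, his_new, _ = _spawn_metamorphs(
            clutch, off_his, scenario, draw, env, rng, density_dependent
        )
        n_metamorphs = len(mass_new)
        if n_metamorphs:
            ids_new = np.arange(pop._next_id, pop._next_id + n_metamorphs)
            recruits = (ids_new, sex_new, mass_new, his_new)

    if recruits is not None:
        ids_new, sex_new, mass_new, his_new = recruits
        pop = Population(
            np.concatenate([pop.ids, ids_new]),
            np.concatenate([pop.sex, sex_new]),
            np.concatenate([pop.age, np.zeros(n_metamorphs, dtype=np.int64)]),
            np.concatenate([pop.mass, mass_new]),
            np.concatenate([pop.his, his_new]),
            np.concatenate([pop.mature, np.zeros(n_metamorphs, dtype=bool)]),
            next_id=pop._next_id + n_metamorphs,
        )

    # adult cap (density-dependent / stochastic modes only)
    if capped and pop.n_adults > scenario.adult_cap:
        adult_idx = np.flatnonzero(pop.mature)
        drop = rng.choice(adult_idx, size=pop.n_adults - scenario.adult_cap, replace=False)
        keep = np.ones(pop.size, dtype=bool)
        keep[drop] = False
        pop = pop.subset(keep)

    record = YearRecord(
        year=year,
        n_total=pop.size,
        n_adults=pop.n_adults,
        n_metamorphs=n_metamorphs,
        mean_his=pop.mean_his(),
        n_removed=n_removed,
    )
    return pop, record
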