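"""Vital-rate parameter draws, rainfall series, synthesis, and CSV I/O.

A :class:`ParameterDraw` bundles one complete set of vital-rate coefficients
— the unit of uncertainty propagation.  Running the same simulation once per
draw propagates parameter uncertainty (originally Bayesian posterior
uncertainty) through every derived population statistic.  Real coefficient
sets fitted elsewhere can be supplied through the documented CSV schema;
the synthetic generator here emulates their statistical structure
(independent between-draw variation per link-scale coefficient) so the whole
pipeline runs without external data.

Rainfall enters the stochastic (viability) model as yearly cumulative
precipitation over two windows: December–January (drives the fraction of
females that emerge to breed) and October–June (drives larval survival to
metamorphosis).  The synthetic rainfall generator is bivariate log-normal:
positive, right-skewed, with wet/dry years correlated across the two windows.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FittingError, SchemaError

__all__ = [
    "ParameterDraw",
    "RainfallYear",
    "SyntheticConfig",
    "DEFAULT_SPREADS",
    "generate_parameter_draws",
    "generate_rainfall_series",
    "sample_rainfall_year",
    "fit_hydro_his_regressions",
    "read_parameter_draws",
    "write_parameter_draws",
    "read_rainfall",
    "write_rainfall",
    "draws_to_frame",
    "frame_to_draws",
    "mean_draw",
]


@dataclass(frozen=True)
class ParameterDraw:
    """One complete coefficient set for all demographic functions.

    Probabilities (post-metamorphic survival, maturation, larval survival,
    breeding fraction) are parameterized on the logit scale; growth,
    fertility, and metamorph mass are linear on the identity scale.
    Mass, hydroperiod, and rainfall covariates enter centered (constants
    ``mass_center``, ``hydro_center``, ``rain_center`` stored alongside the
    coefficients so coefficient sets are portable between data sources).

    Default values are the shipped synthetic coefficient set: an
    order-of-magnitude-realistic parameterization for a pond-breeding
    *Ambystoma* population, chosen so that the 120-day all-native scenario
    grows (lambda > 1) while the 80-day scenario declines (see
    docs/methods.md for the calibration rationale).
    """

    iteration_id: int = 0

    # post-metamorphic annual survival: logit(s) = a + b * (mass - mass_center)
    surv_intercept: float = 0.9
    surv_mass_slope: float = 0.05

    # growth kernel: mass' ~ Normal(a + b * mass, growth_sd)
    growth_intercept: float = 7.0
    growth_slope: float = 0.70
    growth_sd: float = 1.5

    # maturation: logit(p) = a + b * (mass - mass_center); absorbing once attained
    maturity_intercept: float = 0.5
    maturity_mass_slope: float = 0.5

    # fertility (clutch size, eggs): max(0, a + b * mass)
    fert_intercept: float = -200.0
    fert_mass_slope: float = 40.0

    # baseline per-adult annual breeding probability
    breeding_prob: float = 0.65

    # larval survival to metamorphosis:
    # logit(S) = a + b_h*(hydro - hydro_center) + b_g*HIS + b_hg*(hydro-c)*HIS
    larv_intercept: float = -6.5
    larv_hydro_slope: float = 0.10
    larv_his_slope: float = 1.2
    larv_hydro_his_interaction: float = 0.0

    # metamorph mass (g): Normal(a + b_h*(hydro - hydro_center) + b_g*HIS, meta_sd)
    meta_intercept: float = 8.0
    meta_hydro_slope: float = 0.05
    meta_his_slope: float = 1.0
    meta_sd: float = 1.0

    # density dependence: ln-survival and ln-mass shift linearly with
    # ln(egg density / ref_egg_density); slopes are <= 0
    dd_surv_slope: float = -0.7
    dd_mass_slope: float = -0.1
    ref_egg_density: float = 25.0  # eggs m^-3 at which adjustments are identity

    # breeding fraction vs Dec–Jan rainfall:
    # logit(f) = a + b * (dec_jan_mm - rain_center)
    rain_breed_intercept: float = 0.7
    rain_breed_slope: float = 0.01

    # centering constants (constant across draws from one source)
    mass_center: float = 15.0
    hydro_center: float = 100.0
    rain_center: float = 150.0

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` on any violated invariant."""
        if not 0.0 <= self.breeding_prob <= 1.0:
            raise ConfigurationError(
                f"breeding_prob must be in [0, 1], got {self.breeding_prob}"
            )
        for name in ("growth_sd", "meta_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("dd_surv_slope", "dd_mass_slope"):
            if getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be <= 0, got {getattr(self, name)}")
        if self.ref_egg_density <= 0:
            raise ConfigurationError(
                f"ref_egg_density must be > 0, got {self.ref_egg_density}"
            )
        for name in fields(self):
            value = getattr(self, name.name)
            if not math.isfinite(float(value)):
                raise ConfigurationError(f"{name.name} is not finite: {value}")

    def stationary_mass(self) -> float:
        """Fixed point of the mean growth kernel (adult asymptotic mass, g)."""
        if self.growth_slope >= 1.0:
            return self.mass_center
        return self.growth_intercept / (1.0 - self.growth_slope)


_DRAW_FIELDS = [f.name for f in fields(ParameterDraw)]
_COEF_FIELDS = [f for f in _DRAW_FIELDS if f != "iteration_id"]

# Strictly-positive coefficients get log-normal between-draw variation
# (spread interpreted as SD of the natural log); probabilities get
# logit-normal variation; sign-constrained density slopes are clipped at 0.
_LOGNORMAL_FIELDS = frozenset({"growth_sd", "meta_sd", "ref_egg_density"})
_LOGITNORMAL_FIELDS = frozenset({"breeding_prob"})
_NONPOSITIVE_FIELDS = frozenset({"dd_surv_slope", "dd_mass_slope"})
_FIXED_FIELDS = frozenset({"mass_center", "hydro_center", "rain_center"})

#: Default between-draw spreads for the shipped synthetic posterior stand-in.
#: Roughly 5–20% relative variation per coefficient; centering constants fixed.
DEFAULT_SPREADS: dict[str, float] = {
    "surv_intercept": 0.10,
    "surv_mass_slope": 0.005,
    "growth_intercept": 0.20,
    "growth_slope": 0.010,
    "growth_sd": 0.05,
    "maturity_intercept": 0.10,
    "maturity_mass_slope": 0.02,
    "fert_intercept": 10.0,
    "fert_mass_slope": 2.0,
    "breeding_prob": 0.10,
    "larv_intercept": 0.25,
    "larv_hydro_slope": 0.008,
    "larv_his_slope": 0.15,
    "larv_hydro_his_interaction": 0.0,
    "meta_intercept": 0.30,
    "meta_hydro_slope": 0.005,
    "meta_his_slope": 0.15,
    "meta_sd": 0.05,
    "dd_surv_slope": 0.05,
    "dd_mass_slope": 0.02,
    "ref_egg_density": 0.10,
    "rain_breed_intercept": 0.10,
    "rain_breed_slope": 0.002,
}


@dataclass(frozen=True)
class RainfallYear:
    """Yearly cumulative precipitation over the two biologically relevant windows."""

    year_id: int
    dec_jan_mm: float
    oct_jun_mm: float

    def validate(self) -> None:
        for name in ("dec_jan_mm", "oct_jun_mm"):
            v = float(getattr(self, name))
            if not math.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Settings for the synthetic parameter-draw and rainfall generators.

    ``mean`` supplies the central coefficient values; ``spreads`` the
    between-draw variation per coefficient (fields absent from the mapping
    get the package default; map a field to 0 to pin it).  Rainfall is
    bivariate log-normal: medians ``exp(log-mean)``, log-scale SDs, and a
    shared correlation between the December–January and October–June windows.
    """

    n_draws: int = 500
    mean: ParameterDraw = field(default_factory=ParameterDraw)
    spreads: dict[str, float] | None = None
    rain_dec_jan_log_mean: float = math.log(180.0)
    rain_dec_jan_log_sd: float = 0.50
    rain_oct_jun_log_mean: float = math.log(600.0)
    rain_oct_jun_log_sd: float = 0.35
    rain_correlation: float = 0.8
    rng_seed: int = 0

    def resolved_spreads(self) -> dict[str, float]:
        out = dict(DEFAULT_SPREADS)
        if self.spreads is not None:
            unknown = set(self.spreads) - set(_COEF_FIELDS)
            if unknown:
                raise ConfigurationError(f"unknown coefficient names in spreads: {sorted(unknown)}")
            out.update(self.spreads)
        return out

    def validate(self) -> None:
        if self.n_draws < 1:
            raise ConfigurationError(f"n_draws must be >= 1, got {self.n_draws}")
        for name, sd in self.resolved_spreads().items():
            if sd < 0:
                raise ConfigurationError(f"spread for {name} must be >= 0, got {sd}")
        if not -1.0 <= self.rain_correlation <= 1.0:
            raise ConfigurationError(
                f"rain_correlation must be in [-1, 1], got {self.rain_correlation}"
            )
        if self.rain_dec_jan_log_sd < 0 or self.rain_oct_jun_log_sd < 0:
            raise ConfigurationError("rainfall log-spreads must be >= 0")
        self.mean.validate()


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def generate_parameter_draws(config: SyntheticConfig) -> list[ParameterDraw]:
    """Sample ``config.n_draws`` coefficient sets around the configured means.

    Between-draw variation is independent per coefficient: normal on the
    coefficient's natural (link) scale, log-normal for strictly-positive
    quantities, logit-normal for probabilities, and clipped at zero for the
    sign-constrained density slopes.  A fixed ``rng_seed`` makes the output
    a pure function of the configuration.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    spreads = config.resolved_spreads()
    n = config.n_draws

    columns: dict[str, np.ndarray] = {}
    for name in _COEF_FIELDS:
        mu = float(getattr(config.mean, name))
        if name in _FIXED_FIELDS:
            columns[name] = np.full(n, mu)
            continue
        sd = spreads.get(name, 0.0)
        z = rng.standard_normal(n)
        if name in _LOGNORMAL_FIELDS:
            vals = np.exp(np.log(mu) + sd * z) if mu > 0 else np.full(n, mu)
        elif name in _LOGITNORMAL_FIELDS:
            if 0.0 < mu < 1.0:
                from scipy.special import expit

                vals = expit(_logit(mu) + sd * z)
            else:
                vals = np.full(n, mu)
        else:
            vals = mu + sd * z
            if name in _NONPOSITIVE_FIELDS:
                vals = np.minimum(vals, 0.0)
        columns[name] = vals

    draws = []
    for i in range(n):
        kwargs = {name: float(columns[name][i]) for name in _COEF_FIELDS}
        draw = ParameterDraw(iteration_id=i + 1, **kwargs)
        draw.validate()
        draws.append(draw)
    return draws


def mean_draw(draws: Sequence[ParameterDraw]) -> ParameterDraw:
    """Coefficient-wise mean across draws (the 'posterior mean' parameter set)."""
    if not draws:
        raise ConfigurationError("cannot average an empty draw collection")
    kwargs = {
        name: float(np.mean([getattr(d, name) for d in draws])) for name in _COEF_FIELDS
    }
    # means of valid draws can violate nothing except via floating error
    kwargs["dd_surv_slope"] = min(kwargs["dd_surv_slope"], 0.0)
    kwargs["dd_mass_slope"] = min(kwargs["dd_mass_slope"], 0.0)
    return ParameterDraw(iteration_id=0, **kwargs)


def generate_rainfall_series(config: SyntheticConfig, n_years: int) -> list[RainfallYear]:
    """Draw ``n_years`` of correlated, right-skewed synthetic precipitation."""
    config.validate()
    if n_years < 1:
        raise ConfigurationError(f"n_years must be >= 1, got {n_years}")
    rng = np.random.default_rng(config.rng_seed)
    rho = config.rain_correlation
    z1 = rng.standard_normal(n_years)
    z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(n_years)
    dec_jan = np.exp(config.rain_dec_jan_log_mean + config.rain_dec_jan_log_sd * z1)
    oct_jun = np.exp(config.rain_oct_jun_log_mean + config.rain_oct_jun_log_sd * z2)
    series = [
        RainfallYear(year_id=i + 1, dec_jan_mm=float(dec_jan[i]), oct_jun_mm=float(oct_jun[i]))
        for i in range(n_years)
    ]
    for year in series:
        year.validate()
    return series


def sample_rainfall_year(series: Sequence[RainfallYear], rng: np.random.Generator) -> RainfallYear:
    """Uniformly sample one historical year, with replacement."""
    if len(series) == 0:
        raise ConfigurationError("rainfall series is empty")
    return series[int(rng.integers(0, len(series)))]


# ---------------------------------------------------------------------------
# Regression stand-in for the hydroperiod x HIS experiment fits
# ---------------------------------------------------------------------------

def fit_hydro_his_regressions(
    rows: pd.DataFrame,
    n_draws: int,
    rng: np.random.Generator,
    hydro_center: float = 100.0,
) -> pd.DataFrame:
    """Fit larval-survival and metamorph-mass regressions, with uncertainty.

    ``rows`` must have columns ``hydroperiod_days`` and ``his`` plus at least
    one of ``survived`` (0/1: logistic regression on the logit scale) and
    ``metamorph_mass`` (g: ordinary least squares).  The point fit is maximum
    likelihood; between-draw variation is a parametric bootstrap (simulate
    responses from the fitted model, refit, repeat), which emulates posterior
    draws without a sampler.  ``n_draws == 1`` returns the point fit itself.

    Returns a DataFrame with one row per draw and the fitted coefficient
    columns (``larv_*`` and/or ``meta_*``), hydroperiod centered at
    ``hydro_center``.
    """
    import statsmodels.api as sm

    required = {"hydroperiod_days", "his"}
    missing = required - set(rows.columns)
    if missing:
        raise SchemaError(f"experiment rows missing columns: {sorted(missing)}")
    if len(rows) < 10:
        raise FittingError(f"need >= 10 experiment rows, got {len(rows)}")
    if rows["hydroperiod_days"].nunique() < 2:
        if rows["his"].nunique() < 2:
            raise FittingError(
                "degenerate design: single hydroperiod and single HIS value"
            )
        raise FittingError("experiment rows must span >= 2 hydroperiod values")

    has_surv = "survived" in rows.columns
    has_mass = "metamorph_mass" in rows.columns
    if not (has_surv or has_mass):
        raise SchemaError("need a 'survived' or 'metamorph_mass' response column")

    x = np.column_stack(
        [np.asarray(rows["hydroperiod_days"], float) - hydro_center, np.asarray(rows["his"], float)]
    )
    X = sm.add_constant(x)

    out: dict[str, np.ndarray] = {}

    if has_surv:
        y = np.asarray(rows["survived"], float)
        if np.all(y == y[0]):
            raise FittingError(
                "complete separation: all experiment outcomes identical "
                f"(survived = {y[0]:g})"
            )
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        fit = glm.fit()
        if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(fit.params) > 50):
            raise FittingError("logistic fit diverged (quasi-separation suspected)")
        if n_draws == 1:
            boot = fit.params[None, :]
        else:
            p_hat = fit.fittedvalues
            boot = np.empty((n_draws, 3))
            for b in range(n_draws):
                y_star = rng.binomial(1, p_hat)
                if np.all(y_star == y_star[0]):  # resampled separation: redraw
                    y_star[0] = 1 - y_star[0]
                boot[b] = sm.GLM(y_star, X, family=sm.families.Binomial()).fit().params
        out["larv_intercept"] = boot[:, 0]
        out["larv_hydro_slope"] = boot[:, 1]
        out["larv_his_slope"] = boot[:, 2]

    if has_mass:
        y = np.asarray(rows["metamorph_mass"], float)
        fit = sm.OLS(y, X).fit()
        sigma = float(np.sqrt(fit.scale))
        if n_draws == 1:
            boot = np.concatenate([fit.params, [sigma]])[None, :]
        else:
            mu_hat = fit.fittedvalues
            boot = np.empty((n_draws, 4))
            for b in range(n_draws):
                y_star = mu_hat + rng.normal(0.0, sigma, size=len(y))
                refit = sm.OLS(y_star, X).fit()
                boot[b] = np.concatenate([refit.params, [np.sqrt(refit.scale)]])
        out["meta_intercept"] = boot[:, 0]
        out["meta_hydro_slope"] = boot[:, 1]
        out["meta_his_slope"] = boot[:, 2]
        out["meta_sd"] = boot[:, 3]

    frame = pd.DataFrame(out)
    frame.insert(0, "iteration_id", np.arange(1, n_draws + 1))
    return frame


# ---------------------------------------------------------------------------
# CSV I/O (RFC-4180 with header row; full-precision round trip)
# ---------------------------------------------------------------------------



def draws_to_frame(draws: Sequence[ParameterDraw]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(d) for d in draws], columns=_DRAW_FIELDS)


def frame_to_draws(frame: pd.DataFrame) -> list[ParameterDraw]:
    draws = []
    for idx, row in frame.iterrows():
        kwargs = {name: row[name] for name in _DRAW_FIELDS}
        kwargs["iteration_id"] = int(kwargs["iteration_id"])
        draw = ParameterDraw(**{k: (v if k == "iteration_id" else float(v)) for k, v in kwargs.items()})
        try:
            draw.validate()
        except ConfigurationError as exc:
            raise SchemaError(f"row {idx}: {exc}") from exc
        draws.append(draw)
    return draws


def _read_numeric_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if len(frame) == 0:
        raise SchemaError(f"{path}: no data rows")
    for col in required:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{path}: non-numeric value {frame[col][row]!r} at row {row}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise SchemaError(f"{path}: missing value at row {row}, column {col!r}")
        frame[col] = coerced
    return frame


def write_parameter_draws(draws: Sequence[ParameterDraw], path) -> None:
    draws_to_frame(draws).to_csv(path, index=False)


def read_parameter_draws(path) -> list[ParameterDraw]:
    frame = _read_numeric_csv(path, _DRAW_FIELDS)
    return frame_to_draws(frame)


def write_rainfall(series: Sequence[RainfallYear], path) -> None:
    frame = pd.DataFrame(
        [dataclasses.asdict(r) for r in series], columns=["year_id", "dec_jan_mm", "oct_jun_mm"]
    )
    frame.to_csv(path, index=False)


def read_rainfall(path) -> list[RainfallYear]:
    frame = _read_numeric_csv(path, ["year_id", "dec_jan_mm", "oct_jun_mm"])
    series = []
    for idx, row in frame.iterrows():
        year = RainfallYear(
            year_id=int(row["year_id"]),
            dec_jan_mm=float(row["dec_jan_mm"]),
            oct_jun_mm=float(row["oct_jun_mm"]),
        )
        try:
            year.validate()
        except ConfigurationError as exc:
            raise SchemaError(f"{path}: row {idx}: {exc}") from exc
        series.append(year)
    return series
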