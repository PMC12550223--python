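"""Pure demographic-rate functions.

Each function maps individual state (body mass in grams, age, hybrid index
score HIS in [0, 1]), pond environment (hydroperiod in days, egg density in
eggs per cubic metre, rainfall in mm), and one coefficient set
(:class:`~pondipm.params.ParameterDraw`) to a survival probability, a mass,
or a reproductive quantity.  All functions accept scalars or numpy arrays
and are deterministic given their inputs except where an explicit random
generator is taken (growth and metamorph-mass kernels).

Scientific structure:

* probabilities use a logit link; growth, fertility, and metamorph mass are
  linear (identity link) with covariates centered at the constants carried
  by the coefficient set;
* density dependence acts log-log: ln(survival) and ln(mass) shift linearly
  with ln(egg density), anchored so the adjustment is the exact identity at
  the reference egg density;
* rainfall enters twice — the December–January total sets the fraction of
  females that breed (logit-linear), and the October–June total sets the
  fraction of late-stage larvae that metamorphose through a continuous
  piecewise-linear ramp between complete reproductive failure (<= 404.5 mm)
  and complete success (>= 674.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError
from .params import ParameterDraw

__all__ = [
    "EnvironmentYear",
    "MASS_FLOOR_G",
    "MAX_AGE_YEARS",
    "LOWER_RAIN_KNOT_MM",
    "UPPER_RAIN_KNOT_MM",
    "post_metamorphic_survival",
    "grow",
    "maturation_probability",
    "fertility",
    "larval_survival",
    "metamorph_mass",
    "density_adjusted_survival",
    "density_adjusted_mass",
    "breeding_fraction_from_rainfall",
    "metamorph_fraction_from_rainfall",
]

#: Smallest mass (g) any kernel draw may return; sub-floor draws are truncated.
MASS_FLOOR_G = 0.5

#: Individuals older than this are coded dead during the survival step.
MAX_AGE_YEARS = 15

#: October–June precipitation (mm) below which no larvae metamorphose.
LOWER_RAIN_KNOT_MM = 404.5
#: October–June precipitation (mm) above which all late-stage larvae metamorphose.
UPPER_RAIN_KNOT_MM = 674.5


@dataclass(frozen=True)
class EnvironmentYear:
    """Pond environment for one simulated year.

    ``dec_jan_mm`` and ``oct_jun_mm`` are present only in stochastic
    (viability) runs; ``egg_density`` may override the internally computed
    egg density in density-dependent runs and must be absent otherwise.
    """

    hydroperiod_days: float
    dec_jan_mm: float | None = None
    oct_jun_mm: float | None = None
    egg_density: float | None = None

    def validate(self) -> None:
        if self.hydroperiod_days <= 0:
            raise ConfigurationError(
                f"hydroperiod_days must be > 0, got {self.hydroperiod_days}"
            )
        if self.egg_density is not None and self.egg_density < 0:
            raise ConfigurationError(f"egg_density must be >= 0, got {self.egg_density}")


def _check_positive_mass(mass_g) -> np.ndarray:
    mass = np.asarray(mass_g, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass_g must be > 0")
    return mass


def _check_his(his) -> np.ndarray:
    h = np.asarray(his, dtype=float)
    if np.any((h < 0) | (h > 1)):
        raise ValueError("his must lie in [0, 1]")
    return h


def post_metamorphic_survival(mass_g, age_years, draw: ParameterDraw):
    """Annual survival probability of a post-metamorphic individual.

    Logit-linear in centered mass; identically zero past the maximum age
    (individuals older than 15 are coded dead).
    """
    mass = _check_positive_mass(mass_g)
    age = np.asarray(age_years)
    p = expit(draw.surv_intercept + draw.surv_mass_slope * (mass - draw.mass_center))
    p = np.where(age > MAX_AGE_YEARS, 0.0, p)
    return p if p.ndim else float(p)

def grow(mass_g, draw: ParameterDraw, rng: np.random.Generator):
    """Draw next-year mass from the growth kernel, floored at a small positive mass."""
    mass = _check_positive_mass(mass_g)
    mean = draw.growth_intercept + draw.growth_slope * mass
    new = mean + (rng.normal(0.0, draw.growth_sd, size=mass.shape) if draw.growth_sd > 0 else 0.0)
    new = np.maximum(new, MASS_FLOOR_G)
    return new if np.ndim(new) else float(new)

def maturation_probability(mass_g, draw: ParameterDraw):
    """Probability an immature individual matures this year (maturity is absorbing)."""
    mass = _check_positive_mass(mass_g)
    p = expit(draw.maturity_intercept + draw.maturity_mass_slope * (mass - draw.mass_center))
    return p if p.ndim else float(p)

def fertility(mass_g, draw: ParameterDraw):
    """Expected clutch size (eggs) as a linear function of mass, truncated at zero."""
    mass = _check_positive_mass(mass_g)
    eggs = np.maximum(0.0, draw.fert_intercept + draw.fert_mass_slope * mass)
    return eggs if eggs.ndim else float(eggs)


def larval_survival(hydroperiod_days, his, draw: ParameterDraw):
    """Survival of larvae to metamorphosis given pond hydroperiod and offspring HIS.

    Logit-linear with centered hydroperiod, HIS, and an optional
    hydroperiod x HIS interaction (default 0).  Longer hydroperiods and —
    with the shipped positive slope — higher non-native ancestry both
    increase survival.
    """
    hydro = np.asarray(hydroperiod_days, dtype=float)
    if np.any(hydro <= 0):
        raise ValueError("hydroperiod_days must be > 0")
    h = _check_his(his)
    dh = hydro - draw.hydro_center
    logit = (
        draw.larv_intercept
        + draw.larv_hydro_slope * dh
        + draw.larv_his_slope * h
        + draw.larv_hydro_his_interaction * dh * h
    )
    p = expit(logit)
    return p if np.ndim(p) else float(p)


def metamorph_mass(hydroperiod_days, his, draw: ParameterDraw, rng: np.random.Generator, size=None):
    """Draw mass at metamorphosis (g), linear in centered hydroperiod and HIS."""
    hydro = np.asarray(hydroperiod_days, dtype=float)
    h = _check_his(his)
    mean = (
        draw.meta_intercept
        + draw.meta_hydro_slope * (hydro - draw.hydro_center)
        + draw.meta_his_slope * h
    )
    if size is None:
        size = np.broadcast(hydro, h).shape
    noise = rng.normal(0.0, draw.meta_sd, size=size) if draw.meta_sd > 0 else 0.0
    mass = np.maximum(np.broadcast_to(mean, size) + noise, MASS_FLOOR_G)
    return mass if np.ndim(mass) else float(mass)


def _density_log_shift(egg_density, slope: float, draw: ParameterDraw) -> np.ndarray:
    """ln-scale shift at the given egg density; identity (0) at the reference.

    Zero or near-zero densities are evaluated at a small configured floor
    (ref_egg_density * 1e-3) so the log is defined.
    """
    floor = draw.ref_egg_density * 1e-3
    d = np.maximum(np.asarray(egg_density, dtype=float), floor)
    return slope * (np.log(d) - np.log(draw.ref_egg_density))


def density_adjusted_survival(base_survival, egg_density, draw: ParameterDraw):
    """Re-center larval survival on its hydroperiod/HIS prediction at reference density.

    ln(result) = ln(base) + dd_surv_slope * (ln(density) - ln(reference)),
    clipped into (0, 1].  Exactly ``base_survival`` at the reference density.
    """
    base = np.asarray(base_survival, dtype=float)
    if np.any((base <= 0) | (base > 1)):
        raise ValueError("base_survival must lie in (0, 1]")
    if np.any(np.asarray(egg_density, dtype=float) < 0):
        raise ValueError("egg_density must be >= 0")
    out = np.minimum(np.exp(np.log(base) + _density_log_shift(egg_density, draw.dd_surv_slope, draw)), 1.0)
    return out if out.ndim else float(out)


def density_adjusted_mass(base_mass_g, egg_density, draw: ParameterDraw):
    """Same log-log re-centering applied to metamorph mass (no upper clip)."""
    base = _check_positive_mass(base_mass_g)
    if np.any(np.asarray(egg_density, dtype=float) < 0):
        raise ValueError("egg_density must be >= 0")
    out = np.exp(np.log(base) + _density_log_shift(egg_density, draw.dd_mass_slope, draw))
    return out if out.ndim else float(out)


def breeding_fraction_from_rainfall(dec_jan_mm, draw: ParameterDraw):
    """Fraction of mature females that emerge to breed, vs Dec–Jan precipitation."""
    rain = np.asarray(dec_jan_mm, dtype=float)
    if np.any(rain < 0):
        raise ValueError("dec_jan_mm must be >= 0")
    f = expit(draw.rain_breed_intercept + draw.rain_breed_slope * (rain - draw.rain_center))
    return f if f.ndim else float(f)


def metamorph_fraction_from_rainfall(oct_jun_mm):
    """Proportion of late-stage larvae that successfully metamorphose.

    Three-component piecewise-linear ramp in October–June precipitation:
    0 at or below 404.5 mm (complete reproductive failure), 1 at or above
    674.5 mm, linear and continuous in between.
    """
    rain = np.asarray(oct_jun_mm, dtype=float)
    if np.any(rain < 0):
        raise ValueError("oct_jun_mm must be >= 0")
    frac = np.interp(rain, [LOWER_RAIN_KNOT_MM, UPPER_RAIN_KNOT_MM], [0.0, 1.0])
    return frac if frac.ndim else float(frac)
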